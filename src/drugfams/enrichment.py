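"""Per-drug overrepresentation of targets in protein families.

For a drug with target set T and a family with relatives P drawn from a
universe of N proteins, the number of targets that are relatives of the
family is modelled as Binomial(|T|, P_FF) with P_FF = n_FF / N.  A family is
*overrepresented* when the observed overlap exceeds the expectation
|T| * P_FF, and the association is *significant* when the two-sided binomial
p-value survives Benjamini-Hochberg FDR control over the whole batch of
(drug, family) tests.  Families with at least one significant association
are called druggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DrugProfile, FamilyTable

__all__ = [
    "EnrichmentRecord",
    "expected_overlap",
    "binom_two_sided",
    "test_drug_family",
    "bh_adjust",
    "run_enrichment",
]

# Outcomes whose probability is within this relative tolerance of the
# observed outcome's probability count as "at least as extreme"; this is the
# convention of R's binom.test and reproduces printed worked examples.
_REL_TOL = 1.0 + 1e-7


@dataclass
class EnrichmentRecord:
    """Outcome of one (drug, family) binomial overrepresentation test."""

    drug_id: str
    family_id: str
    n_ff: int
    p_ff: float
    success: int
    trials: int
    expected: float  # the overrepresentation threshold, trials * p_ff
    p_value: float
    q_value: float = float("nan")
    significant: bool = False

    @property
    def overrepresented(self) -> bool:
        return self.success > self.expected


def expected_overlap(trials: int, n_ff: int, universe_size: int) -> float:
    """Expected number of a drug's targets that are relatives of a family.

    This is the overrepresentation threshold: observing more than
    trials * n_ff / universe_size targets in the family means the family is
    overrepresented in the drug's targets.
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if not (0 < n_ff <= universe_size):
        raise ValueError(f"need 0 < n_ff <= universe_size, got {n_ff}/{universe_size}")
    if trials < 0:
        raise ValueError("trials must be non-negative")
    return trials * n_ff / universe_size


def binom_two_sided(success: int, trials: int, p: float) -> float:
    """Minimum-likelihood two-sided binomial test p-value.

    Sums Pr(X = k) over every outcome k whose probability does not exceed
    that of the observed count (up to a 1e-7 relative tolerance for
    floating-point ties), the convention of R's binom.test.  The result is
    clamped to (0, 1].
    """
    if not 0 <= success <= trials:
        raise ValueError(f"need 0 <= success <= trials, got {success}/{trials}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"success probability {p} outside [0, 1]")
    if p == 0.0:
        return 1.0 if success == 0 else 0.0
    if p == 1.0:
        return 1.0 if success == trials else 0.0
    k = np.arange(trials + 1)
    pmf = stats.binom.pmf(k, trials, p)
    d = pmf[success]
    pval = float(pmf[pmf <= d * _REL_TOL].sum())
    return min(max(pval, np.nextafter(0.0, 1.0)), 1.0)


def test_drug_family(
    profile: DrugProfile,
    family_id: str,
    family_table: FamilyTable,
) -> EnrichmentRecord:
    """Test whether a drug's targets are overrepresented among a family's
    relatives.  q_value/significant are filled in later by the batch BH step.
    """
    relatives = family_table.families[family_id]
    trials = len(profile.targets)
    if trials == 0:
        raise ValueError(f"drug {profile.drug_id} has no targets to test")
    n_ff = len(relatives)
    n_universe = len(family_table.universe)
    p_ff = n_ff / n_universe
    success = len(profile.targets & relatives)
    return EnrichmentRecord(
        drug_id=profile.drug_id,
        family_id=family_id,
        n_ff=n_ff,
        p_ff=p_ff,
        success=success,
        trials=trials,
        expected=expected_overlap(trials, n_ff, n_universe),
        p_value=binom_two_sided(success, trials, p_ff) if p_ff < 1.0 else 1.0,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    if len(p_values) == 0:
        return []
    arr = np.asarray(p_values, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return q.tolist()


def run_enrichment(
    profiles: Mapping[str, DrugProfile],
    family_table: FamilyTable,
    q_threshold: float = 0.001,
    universe: str = "all",
    adjust_scope: str = "batch",
    families_per_drug: str = "hit",
) -> tuple[list[EnrichmentRecord], set[str]]:
    """Run the full enrichment screen.

    Parameters
    ----------
    universe : {"all", "dataset"}
        "all" uses every protein in the family table's universe as N;
        "dataset" restricts N (and family sizes) to proteins that actually
        appear in the drug profiles, mirroring a screen where the reference
        list is the set of known drug-binding proteins.
    adjust_scope : {"batch", "per_drug"}
        BH correction over all tests at once (default, one global q-value
        scale) or separately within each drug.
    families_per_drug : {"hit", "all"}
        Test only families containing at least one of the drug's targets, or
        every family (zero-success tests are still valid tests).

    Returns the records in deterministic (drug, family) order plus the set
    of druggable families (>= 1 association at q < q_threshold).
    """
    if universe not in ("all", "dataset"):
        raise ValueError(f"unknown universe mode {universe!r}")
    if adjust_scope not in ("batch", "per_drug"):
        raise ValueError(f"unknown adjust_scope {adjust_scope!r}")
    table = family_table
    if universe == "dataset":
        seen: set[str] = set()
        for prof in profiles.values():
            seen |= prof.targets | prof.off_targets
        table = family_table.restrict_universe(seen)

    records: list[EnrichmentRecord] = []
    for drug in sorted(profiles):
        prof = profiles[drug]
        if not prof.targets:
            continue
        if families_per_drug == "all":
            fams = sorted(table.families)
        else:
            fams = sorted(f for f in prof.family_profile if f in table.families)
        for fam in fams:
            records.append(test_drug_family(prof, fam, table))

    if records:
        if adjust_scope == "batch":
            qs = bh_adjust([r.p_value for r in records])
            for rec, q in zip(records, qs):
                rec.q_value = q
        else:
            by_drug: dict[str, list[EnrichmentRecord]] = {}
            for rec in records:
                by_drug.setdefault(rec.drug_id, []).append(rec)
            for recs in by_drug.values():
                for rec, q in zip(recs, bh_adjust([r.p_value for r in recs])):
                    rec.q_value = q
        for rec in records:
            rec.significant = bool(rec.q_value < q_threshold and rec.overrepresented)

    druggable = {r.family_id for r in records if r.significant}
    return records, druggable
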