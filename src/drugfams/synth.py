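"""Synthetic world generator with recorded ground truth.

Emulates the structure the analysis pipeline assumes in real data:

* Zipf-like family sizes over a protein universe, with a configurable
  fraction of proteins holding a second family membership (family tables
  are many-to-many in practice).
* A weighted functional network in which a subset of families is planted as
  dense high-confidence modules while the remaining families — including
  the very large, functionally diffuse ones — scatter over the background.
* "Coherent" drugs whose targets concentrate in one module family (their
  home family) versus scattered drugs whose targets spread uniformly;
  off-targets are only loosely clustered around the home module.  Targeted
  proteins additionally receive a few high-confidence cross-module edges,
  making them bridge modules the way hubs do.
* Fingerprints derived from a per-family prototype bit pattern, so drugs
  sharing a home family are structurally similar — the plantable
  similarity-property-principle signal.
* Side effects: families in tight network neighbourhoods are more likely to
  be free of flagged proteins (logistic link), and per-drug adverse-event
  counts grow with target dispersion (Poisson with rate
  sidefx_base + sidefx_dispersion_gain * (1 - target matrix similarity)).

Everything is reproducible from (config, seed); ground truth records every
planted signal so recovery can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ActivityRecord,
    FamilyTable,
    SideEffectTable,
    write_activity_table,
    write_family_table,
    write_side_effects,
)
from .network import FunctionalNetwork, matrix_similarity, write_network
from .similarity import Fingerprint, write_fingerprints

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticWorld", "generate_world", "generate_network"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world; defaults give a desk-scale data set
    with clearly planted but noisy structure."""

    n_proteins: int = 400
    n_families: int = 30
    family_size_exponent: float = 1.2  # Zipf exponent for family sizes
    secondary_membership_frac: float = 0.10
    frac_module_families: float = 0.5  # fraction of cap-eligible families planted as modules
    module_size_cap: int = 30  # families larger than this are always diffuse
    n_drugs: int = 60
    frac_coherent_drugs: float = 0.7
    targets_per_drug: tuple[int, int] = (4, 10)
    coherent_fraction: float = 0.8  # fraction of a coherent drug's targets from its home family
    off_targets_per_drug: tuple[int, int] = (3, 8)
    off_target_home_fraction: float = 0.5
    target_hub_degree: int = 2  # extra high-weight cross-module edges per targeted protein
    p_within: float = 0.8
    p_between: float = 0.01
    w_within: tuple[float, float] = (8.0, 2.0)  # Beta(a, b) for within-module edge scores
    w_between: tuple[float, float] = (2.0, 8.0)
    fingerprint_length: int = 166
    fingerprint_density: float = 0.30
    bit_flip_rate: float = 0.05
    sidefx_base: float = 3.0
    sidefx_dispersion_gain: float = 25.0
    # P(family side-effect-free) = logistic(flag_beta0 + flag_beta1 * family score)
    flag_beta0: float = -0.8
    flag_beta1: float = 1.67
    flagged_relative_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "secondary_membership_frac",
            "frac_module_families",
            "frac_coherent_drugs",
            "coherent_fraction",
            "off_target_home_fraction",
            "p_within",
            "p_between",
            "fingerprint_density",
            "bit_flip_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.sidefx_base < 0 or self.sidefx_dispersion_gain < 0:
            raise ValueError("side-effect rate parameters must be non-negative")
        if self.targets_per_drug[0] < 1 or self.targets_per_drug[0] > self.targets_per_drug[1]:
            raise ValueError(f"bad targets_per_drug range {self.targets_per_drug}")


@dataclass
class GroundTruth:
    """Planted structure of a generated world.

    module_families: families planted as dense network modules.
    home_family: drug -> its home (module) family, or None for scattered drugs.
    module_of: protein -> planted module (only proteins inside module families).
    dispersion: drug -> true matrix similarity of its target set.
    family_score: family -> true (median-pairwise) matrix similarity.
    family_free: family -> realized side-effect-free label.
    """

    module_families: set[str]
    home_family: dict[str, str | None]
    module_of: dict[str, str]
    dispersion: dict[str, float]
    family_score: dict[str, float | None]
    family_free: dict[str, bool]


@dataclass
class SyntheticWorld:
    """In-memory bundle of all generated tables plus ground truth."""

    config: SyntheticConfig
    activities: list[ActivityRecord]
    family_table: FamilyTable
    network: FunctionalNetwork
    fingerprints: dict[str, Fingerprint]
    side_effects: SideEffectTable
    drug_metadata: pd.DataFrame  # drug_id, atc_code
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle as the TSV formats the pipeline consumes, plus
        ground-truth TSVs; returns the path of every file written."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "activities": out / "activities.tsv",
            "families": out / "families.tsv",
            "network": out / "network.tsv",
            "fingerprints": out / "fingerprints.tsv",
            "protein_side_effects": out / "protein_side_effects.tsv",
            "drug_side_effects": out / "drug_side_effects.tsv",
            "drug_metadata": out / "drug_metadata.tsv",
            "ground_truth_drugs": out / "ground_truth_drugs.tsv",
            "ground_truth_families": out / "ground_truth_families.tsv",
            "ground_truth_modules": out / "ground_truth_modules.tsv",
        }
        write_activity_table(self.activities, paths["activities"])
        write_family_table(self.family_table, paths["families"])
        write_network(self.network, paths["network"])
        write_fingerprints(self.fingerprints, paths["fingerprints"])
        write_side_effects(
            self.side_effects,
            protein_flags_path=paths["protein_side_effects"],
            drug_counts_path=paths["drug_side_effects"],
        )
        self.drug_metadata.to_csv(paths["drug_metadata"], sep="\t", index=False)
        t = self.truth
        pd.DataFrame(
            [
                {
                    "drug_id": d,
                    "home_family": t.home_family[d] or "",
                    "true_dispersion": t.dispersion.get(d, float("nan")),
                }
                for d in sorted(t.home_family)
            ]
        ).to_csv(paths["ground_truth_drugs"], sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "family_id": f,
                    "is_module": int(f in t.module_families),
                    "true_score": "" if t.family_score[f] is None else t.family_score[f],
                    "side_effect_free": int(t.family_free[f]),
                }
                for f in sorted(t.family_score)
            ]
        ).to_csv(paths["ground_truth_families"], sep="\t", index=False)
        pd.DataFrame(
            [{"protein_id": p, "module": m} for p, m in sorted(t.module_of.items())]
        ).to_csv(paths["ground_truth_modules"], sep="\t", index=False)
        return paths


def _zipf_sizes(n_items: int, n_groups: int, exponent: float, min_size: int = 3) -> np.ndarray:
    """Group sizes proportional to rank^-exponent, summing to n_items."""
    raw = np.arange(1, n_groups + 1, dtype=float) ** (-exponent)
    sizes = np.maximum(min_size, np.round(raw / raw.sum() * n_items)).astype(int)
    # repair the rounding drift on the largest groups
    drift = int(n_items - sizes.sum())
    i = 0
    while drift != 0:
        step = 1 if drift > 0 else -1
        if sizes[i % n_groups] + step >= min_size:
            sizes[i % n_groups] += step
            drift -= step
        i += 1
    return sizes


def _planted_partition_edges(
    proteins: list[str],
    module_of: dict[str, str],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str, float]]:
    """Edge list of a planted-partition weighted graph.

    Pairs whose two proteins share a module are linked with probability
    p_within and weight Beta(w_within); every other pair (including all
    background proteins) with p_between and Beta(w_between).  Weights are
    clipped away from 0 so scores stay in (0, 1].
    """
    labels = np.array([module_of.get(p, f"__bg__{p}") for p in proteins])
    n = len(proteins)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    p_edge = np.where(same, config.p_within, config.p_between)
    keep = rng.random(len(iu)) < p_edge
    a = np.where(same, config.w_within[0], config.w_between[0])
    b = np.where(same, config.w_within[1], config.w_between[1])
    weights = np.clip(rng.beta(a, b), 1e-6, 1.0)
    return [
        (proteins[i], proteins[j], float(w))
        for i, j, w in zip(iu[keep], ju[keep], weights[keep])
    ]


def generate_network(
    module_of: dict[str, str],
    config: SyntheticConfig,
    rng: np.random.Generator,
    background: list[str] | None = None,
) -> FunctionalNetwork:
    """Planted-partition weighted graph over the proteins in *module_of*
    (plus optional background proteins outside any module)."""
    proteins = sorted(set(module_of) | set(background or []))
    return FunctionalNetwork(_planted_partition_edges(proteins, module_of, config, rng))


def generate_world(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticWorld:
    """Generate the full synthetic bundle; deterministic given (config, seed).

    *seed*, when given, overrides ``config.seed``.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    # --- proteins and families -------------------------------------------
    width = len(str(config.n_proteins))
    proteins = [f"P{i:0{width}d}" for i in range(1, config.n_proteins + 1)]
    fam_ids = [f"FF{i:03d}" for i in range(1, config.n_families + 1)]
    sizes = _zipf_sizes(config.n_proteins, config.n_families, config.family_size_exponent)
    order = rng.permutation(config.n_proteins)
    families: dict[str, set[str]] = {}
    primary_family: dict[str, str] = {}
    pos = 0
    for fam, k in zip(fam_ids, sizes):
        members = {proteins[j] for j in order[pos : pos + k]}
        families[fam] = members
        for m in members:
            primary_family[m] = fam
        pos += k

    # plant network modules among the not-too-large families; very large
    # families stay diffuse (functionally heterogeneous grab-bags)
    eligible = [f for f, k in zip(fam_ids, sizes) if k <= config.module_size_cap]
    n_modules = int(round(config.frac_module_families * len(eligible)))
    module_families = set(
        np.array(sorted(eligible))[rng.permutation(len(eligible))[:n_modules]].tolist()
    )
    module_of = {
        p: f for p, f in primary_family.items() if f in module_families
    }

    # secondary memberships: a fraction of proteins join one extra family
    n_secondary = int(round(config.secondary_membership_frac * config.n_proteins))
    for j in rng.choice(config.n_proteins, size=n_secondary, replace=False):
        p = proteins[j]
        other = fam_ids[rng.integers(config.n_families)]
        if other != primary_family[p]:
            families[other].add(p)
    family_table = FamilyTable(
        families={f: frozenset(m) for f, m in families.items()},
        universe=frozenset(proteins),
    )

    # --- drugs and activities --------------------------------------------
    n_coherent = int(round(config.frac_coherent_drugs * config.n_drugs))
    drug_ids = [f"D{i:03d}" for i in range(1, config.n_drugs + 1)]
    home_family: dict[str, str | None] = {}
    drug_targets: dict[str, list[str]] = {}
    activities: list[ActivityRecord] = []
    protein_arr = np.array(proteins)
    lo, hi = config.targets_per_drug
    # home targets are drawn from the module core of the home family so the
    # planted network signal is not diluted by secondary members
    module_core = {f: sorted(families[f] & {p for p, m in module_of.items() if m == f})
                   for f in module_families}

    for d_idx, drug in enumerate(drug_ids):
        coherent = d_idx < n_coherent
        k = int(rng.integers(lo, hi + 1))
        if coherent:
            n_home = max(2, int(round(config.coherent_fraction * k)))
            eligible_homes = [f for f in sorted(module_families) if len(module_core[f]) >= n_home]
            if not eligible_homes:
                raise ValueError(
                    f"infeasible config: no module family can host {n_home} targets "
                    f"(coherent_fraction={config.coherent_fraction}, "
                    f"targets_per_drug={config.targets_per_drug})"
                )
            home = eligible_homes[rng.integers(len(eligible_homes))]
            targets = list(rng.choice(module_core[home], size=n_home, replace=False))
            outside = sorted(set(proteins) - families[home])
            n_out = min(k - n_home, len(outside))
            if n_out > 0:
                targets += list(rng.choice(outside, size=n_out, replace=False))
            home_family[drug] = home
        else:
            targets = list(rng.choice(protein_arr, size=k, replace=False))
            home_family[drug] = None
        drug_targets[drug] = targets

        # off-targets: loosely clustered around the home module for coherent
        # drugs, uniform otherwise
        m = int(rng.integers(config.off_targets_per_drug[0], config.off_targets_per_drug[1] + 1))
        off: list[str] = []
        taken = set(targets)
        if coherent and home_family[drug] is not None:
            module = sorted(set(module_core[home_family[drug]]) - taken)
            n_home_off = min(int(round(config.off_target_home_fraction * m)), len(module))
            off += list(rng.choice(module, size=n_home_off, replace=False))
            taken |= set(off)
        pool = sorted(set(proteins) - taken)
        n_rand_off = min(m - len(off), len(pool))
        if n_rand_off > 0:
            off += list(rng.choice(pool, size=n_rand_off, replace=False))

        for t in targets:
            activities.append(
                ActivityRecord(drug, t, float(np.round(rng.uniform(6.0, 9.0), 2)),
                               therapeutic=True, max_phase=4)
            )
        for o in off:
            activities.append(
                ActivityRecord(drug, o, float(np.round(rng.uniform(1.0, 4.0), 2)),
                               therapeutic=True, max_phase=4)
            )
        # a little mid-affinity noise that must stay unclassified
        for u in rng.choice(sorted(set(proteins) - taken - set(off)), size=1, replace=False):
            activities.append(
                ActivityRecord(drug, str(u), float(np.round(rng.uniform(4.3, 5.7), 2)),
                               therapeutic=True, max_phase=4)
            )

    # --- network ----------------------------------------------------------
    edges = _planted_partition_edges(proteins, module_of, config, rng)
    if config.target_hub_degree > 0:
        # targeted proteins bridge modules: extra high-confidence edges to
        # uniformly drawn partners
        existing = {frozenset((u, v)) for u, v, _ in edges}
        targeted = sorted({t for ts in drug_targets.values() for t in ts})
        for t in targeted:
            partners = rng.choice(protein_arr, size=config.target_hub_degree, replace=False)
            for p in partners:
                p = str(p)
                if p == t or frozenset((t, p)) in existing:
                    continue
                w = float(np.clip(rng.beta(*config.w_within), 1e-6, 1.0))
                edges.append((t, p, w))
                existing.add(frozenset((t, p)))
    network = FunctionalNetwork(edges)

    # --- fingerprints -----------------------------------------------------
    prototypes = {
        f: (rng.random(config.fingerprint_length) < config.fingerprint_density).astype(int)
        for f in fam_ids
    }
    fingerprints: dict[str, Fingerprint] = {}
    for drug in drug_ids:
        home = home_family[drug]
        if home is not None:
            bits = prototypes[home].copy()
            flips = rng.random(config.fingerprint_length) < config.bit_flip_rate
            bits[flips] = 1 - bits[flips]
        else:
            bits = (rng.random(config.fingerprint_length) < config.fingerprint_density).astype(int)
        fingerprints[drug] = Fingerprint(drug_id=drug, bits=tuple(int(b) for b in bits))

    # --- side effects -----------------------------------------------------
    family_score: dict[str, float | None] = {}
    for f in fam_ids:
        family_score[f] = matrix_similarity(families[f], network, "median_pairwise", set_id=f).value

    protein_flags: dict[str, bool] = {p: False for p in proteins}
    family_free: dict[str, bool] = {}
    for f in fam_ids:
        s = family_score[f] if family_score[f] is not None else 0.0
        p_free = 1.0 / (1.0 + np.exp(-(config.flag_beta0 + config.flag_beta1 * s)))
        free = rng.random() < p_free
        if not free:
            # flag among primary members so flags do not cascade through
            # secondary memberships into families drawn as free
            members = sorted(p for p in families[f] if primary_family[p] == f) or sorted(families[f])
            n_flag = max(1, int(round(config.flagged_relative_frac * len(members))))
            for p in rng.choice(members, size=min(n_flag, len(members)), replace=False):
                protein_flags[str(p)] = True
        family_free[f] = free
    # overlapping memberships can flag a protein in a family drawn "free";
    # the recorded truth is the realized label
    for f in fam_ids:
        family_free[f] = not any(protein_flags[p] for p in families[f])

    dispersion: dict[str, float] = {}
    drug_counts: dict[str, int] = {}
    for drug in drug_ids:
        score = matrix_similarity(drug_targets[drug], network, "mean_pairwise", set_id=drug).value
        s = score if score is not None else 0.0
        dispersion[drug] = s
        lam = config.sidefx_base + config.sidefx_dispersion_gain * (1.0 - s)
        drug_counts[drug] = int(rng.poisson(lam))
    side_effects = SideEffectTable(protein_flags=protein_flags, drug_counts=drug_counts)

    # --- metadata ---------------------------------------------------------
    atc_pool = ["L01", "N05", "C07", "J01", "A10"]
    drug_metadata = pd.DataFrame(
        {
            "drug_id": drug_ids,
            "atc_code": [atc_pool[rng.integers(len(atc_pool))] for _ in drug_ids],
        }
    )

    truth = GroundTruth(
        module_families=module_families,
        home_family=home_family,
        module_of=module_of,
        dispersion=dispersion,
        family_score=family_score,
        family_free=family_free,
    )
    return SyntheticWorld(
        config=config,
        activities=activities,
        family_table=family_table,
        network=network,
        fingerprints=fingerprints,
        side_effects=side_effects,
        drug_metadata=drug_metadata,
        truth=truth,
    )
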