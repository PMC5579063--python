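"""Fingerprint similarity, the empirical significance threshold, and the
similarity-property-principle (SPP) analysis.

The SPP states that structurally similar molecules tend to share properties;
here the property is the interaction profile (the set of proteins, or
protein families, a drug binds).  Structural similarity is the Tanimoto
coefficient (Tc) on binary fingerprints; profile similarity is the Jaccard
index; and "structurally similar" is operationalised as Tc above a
data-driven threshold t* where the pooled empirical survival function
1 - F(t) drops to a chosen significance level alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DrugProfile, ParseError, _read_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "Fingerprint",
    "SimilaritySurvey",
    "SPPBin",
    "SPPResult",
    "tanimoto",
    "jaccard",
    "significance_threshold",
    "spp_analysis",
    "read_fingerprints",
    "write_fingerprints",
]


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary molecular fingerprint (166 bits by default,
    MACCS-key sized)."""

    drug_id: str
    bits: tuple[int, ...]

    @classmethod
    def from_bitstring(cls, drug_id: str, s: str) -> "Fingerprint":
        if set(s) - {"0", "1"}:
            raise ValueError(f"fingerprint for {drug_id} contains non-binary characters")
        return cls(drug_id=drug_id, bits=tuple(int(c) for c in s))

    def to_bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(i for i, b in enumerate(self.bits) if b)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient: shared on-bits over union of on-bits.

    Two all-zero fingerprints have no features to compare; the coefficient
    is defined as 0 with a warning.
    """
    if len(a.bits) != len(b.bits):
        raise ValueError(
            f"fingerprint length mismatch: {a.drug_id} has {len(a.bits)}, "
            f"{b.drug_id} has {len(b.bits)}"
        )
    sa, sb = a.on_bits, b.on_bits
    union = len(sa | sb)
    if union == 0:
        logger.warning("tanimoto(%s, %s): both fingerprints empty; returning 0", a.drug_id, b.drug_id)
        return 0.0
    return len(sa & sb) / union


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard index |a & b| / |a | b|; two empty sets give 0 with a warning."""
    sa, sb = set(set_a), set(set_b)
    union = len(sa | sb)
    if union == 0:
        logger.warning("jaccard of two empty sets; returning 0")
        return 0.0
    return len(sa & sb) / union


@dataclass
class SimilaritySurvey:
    """Pooled pairwise Tc sample, its ECDF, and the threshold t* at alpha."""

    tc_values: np.ndarray
    alpha: float
    threshold: float

    def ecdf(self, t: float) -> float:
        return float(np.mean(self.tc_values <= t))


def significance_threshold(
    tc_values: Sequence[float] | np.ndarray,
    alpha: float = 0.005,
) -> SimilaritySurvey:
    """Smallest observed Tc value t with p = 1 - F(t) <= alpha.

    F is the pooled right-continuous empirical CDF of all pairwise Tc
    values; ties share an F value.  If no observed value reaches the level
    (1 - F(t) > alpha for all t < max), the maximum observed value — for
    which 1 - F = 0 — is returned; if even that is impossible the threshold
    is 1.0 with a warning.
    """
    arr = np.sort(np.asarray(tc_values, dtype=float))
    if arr.size == 0:
        raise ValueError("empty Tc sample")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    # survival at each sorted unique value: 1 - F(t)
    uniq, counts = np.unique(arr, return_counts=True)
    cum = np.cumsum(counts)
    surv = 1.0 - cum / arr.size
    hits = np.nonzero(surv <= alpha)[0]
    if hits.size == 0:  # unreachable because surv at max value is 0
        logger.warning("significance level %g unreachable; returning 1.0", alpha)
        return SimilaritySurvey(tc_values=arr, alpha=alpha, threshold=1.0)
    return SimilaritySurvey(tc_values=arr, alpha=alpha, threshold=float(uniq[hits[0]]))


def per_drug_median_threshold(
    tc_by_drug: Mapping[str, Sequence[float]],
    alpha: float = 0.005,
) -> float:
    """Alternative construction: one threshold per drug's own Tc
    distribution, aggregated as the median across drugs."""
    thresholds = [
        significance_threshold(v, alpha).threshold for v in tc_by_drug.values() if len(v)
    ]
    if not thresholds:
        raise ValueError("no drug has any Tc values")
    return float(np.median(thresholds))


@dataclass
class SPPBin:
    """One Tc bin of the SPP analysis: half-open [lo, lo + width) (the last
    bin closes at 1.0), its mean profile Jaccard, and the pair count."""

    lo: float
    mean_jaccard: float
    n_pairs: int


@dataclass
class SPPResult:
    bins: list[SPPBin]
    threshold: float
    mean_jaccard_above: float
    mean_jaccard_below: float
    n_pairs: int
    excluded_drugs: list[str] = field(default_factory=list)
    pairs: pd.DataFrame | None = None


def spp_analysis(
    profiles: Mapping[str, DrugProfile],
    fingerprints: Mapping[str, Fingerprint],
    profile_kind: str = "protein",
    threshold: float | None = None,
    alpha: float = 0.005,
    bin_width: float = 0.01,
    keep_pairs: bool = False,
) -> SPPResult:
    """Relate pairwise structural similarity to interaction-profile overlap.

    For every unordered drug pair with both a fingerprint and a non-empty
    profile of the requested kind ("protein" = target sets, "family" =
    family profiles), computes (Tc, Jaccard), aggregates mean Jaccard in Tc
    bins of width *bin_width*, and reports mean Jaccard above vs below the
    similarity threshold (estimated from the pooled ECDF at *alpha* when not
    supplied).  Drugs lacking a fingerprint or profile are excluded and
    logged.
    """
    if profile_kind not in ("protein", "family"):
        raise ValueError(f"unknown profile_kind {profile_kind!r}")

    excluded = []
    drugs = []
    for drug in sorted(profiles):
        prof = profiles[drug]
        pset = prof.targets if profile_kind == "protein" else prof.family_profile
        if drug not in fingerprints or not pset:
            excluded.append(drug)
            logger.info("spp: excluding %s (missing fingerprint or empty profile)", drug)
            continue
        drugs.append((drug, pset, fingerprints[drug]))

    tcs: list[float] = []
    jacs: list[float] = []
    pair_ids: list[tuple[str, str]] = []
    for i in range(len(drugs)):
        for j in range(i + 1, len(drugs)):
            da, pa, fa = drugs[i]
            db, pb, fb = drugs[j]
            tcs.append(tanimoto(fa, fb))
            jacs.append(jaccard(pa, pb))
            pair_ids.append((da, db))
    tc_arr = np.asarray(tcs)
    jac_arr = np.asarray(jacs)
    if tc_arr.size == 0:
        raise ValueError("no drug pairs available for SPP analysis")

    if threshold is None:
        threshold = significance_threshold(tc_arr, alpha).threshold

    n_bins = int(np.ceil(1.0 / bin_width))
    idx = np.minimum((tc_arr / bin_width).astype(int), n_bins - 1)  # last bin closed at 1.0
    bins = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            bins.append(SPPBin(lo=b * bin_width, mean_jaccard=float(jac_arr[mask].mean()), n_pairs=int(mask.sum())))

    above = tc_arr >= threshold
    return SPPResult(
        bins=bins,
        threshold=float(threshold),
        mean_jaccard_above=float(jac_arr[above].mean()) if above.any() else float("nan"),
        mean_jaccard_below=float(jac_arr[~above].mean()) if (~above).any() else float("nan"),
        n_pairs=int(tc_arr.size),
        excluded_drugs=excluded,
        pairs=pd.DataFrame({"drug_a": [a for a, _ in pair_ids], "drug_b": [b for _, b in pair_ids], "tc": tc_arr, "jaccard": jac_arr})
        if keep_pairs
        else None,
    )


def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    """Read a fingerprint TSV (columns: drug_id, bits as a 0/1 string)."""
    df = _read_tsv(path, ["drug_id", "bits"])
    out: dict[str, Fingerprint] = {}
    for idx, row in df.iterrows():
        try:
            out[str(row["drug_id"])] = Fingerprint.from_bitstring(str(row["drug_id"]), str(row["bits"]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {int(idx) + 2}: {exc}") from None
    return out


def write_fingerprints(fps: Mapping[str, Fingerprint], path: str | Path) -> None:
    pd.DataFrame(
        [{"drug_id": d, "bits": fp.to_bitstring()} for d, fp in sorted(fps.items())],
        columns=["drug_id", "bits"],
    ).to_csv(path, sep="\t", index=False)
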