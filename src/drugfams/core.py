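"""Domain types, affinity classification, interaction profiles, and tabular IO.

The pipeline revolves around three tables: a drug-protein activity table
(pchembl values, i.e. -log10 molar potency), a family membership table
mapping protein families to their member proteins ("relatives"), and
side-effect annotations (per-protein association flags and per-drug adverse
reaction counts).  All files are UTF-8 TSV with a mandatory header line;
lines starting with '#' are ignored.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "InteractionClass",
    "DrugProfile",
    "FamilyTable",
    "SideEffectTable",
    "classify_interactions",
    "build_profiles",
    "read_activity_table",
    "write_activity_table",
    "read_family_table",
    "write_family_table",
    "read_side_effects",
    "write_side_effects",
    "write_enrichment",
    "read_enrichment",
]


class ParseError(ValueError):
    """Raised when an input table cannot be parsed; message names the line."""


class InteractionClass(enum.Enum):
    """Affinity class of an aggregated (drug, protein) pair.

    TARGET: high-affinity binding (pchembl >= 6 by default, i.e. stronger
    than 1 uM).  OFF_TARGET: low-affinity binding (pchembl in [1, 4] by
    default).  UNCLASSIFIED: everything else, including the deliberate gap
    between the two windows.
    """

    TARGET = "target"
    OFF_TARGET = "off_target"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ActivityRecord:
    """One drug-protein affinity measurement.

    pchembl is the negative log10 of a molar half-maximal activity
    (IC50, Ki, ...); 6 corresponds to 1 uM.
    """

    drug_id: str
    protein_id: str
    pchembl: float
    therapeutic: bool | None = None
    max_phase: int | None = None

    def __post_init__(self) -> None:
        if self.pchembl < 0:
            raise ValueError(
                f"negative pchembl {self.pchembl} for ({self.drug_id}, {self.protein_id})"
            )


@dataclass
class DrugProfile:
    """A drug's interaction profile: its targets, off-targets, and the
    families containing at least one of its targets."""

    drug_id: str
    targets: frozenset[str]
    off_targets: frozenset[str]
    family_profile: frozenset[str]

    def __post_init__(self) -> None:
        if self.targets & self.off_targets:
            raise ValueError(
                f"drug {self.drug_id}: targets and off-targets overlap: "
                f"{sorted(self.targets & self.off_targets)}"
            )


@dataclass
class FamilyTable:
    """Many-to-many family -> relatives map plus the protein universe.

    A protein may belong to multiple families.  The universe is the set of
    all proteins eligible to be drawn in the enrichment null; by default it
    is the union of all relatives, but a larger explicit universe may be
    supplied.
    """

    families: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        members = frozenset().union(*self.families.values()) if self.families else frozenset()
        if not self.universe:
            self.universe = members
        elif not members <= self.universe:
            raise ValueError(
                f"{len(members - self.universe)} relatives missing from the declared universe"
            )
        for fam, rel in self.families.items():
            if not rel:
                raise ValueError(f"family {fam} has no relatives")

    def size(self, family_id: str) -> int:
        return len(self.families[family_id])

    def families_of(self, protein_id: str) -> frozenset[str]:
        return frozenset(f for f, rel in self.families.items() if protein_id in rel)

    def restrict_universe(self, proteins: Iterable[str]) -> "FamilyTable":
        """Return a copy whose universe (and relatives) are intersected with
        *proteins* — used for the ``universe=dataset`` enrichment mode."""
        keep = frozenset(proteins)
        fams = {
            f: rel & keep for f, rel in self.families.items() if rel & keep
        }
        return FamilyTable(families=fams, universe=self.universe & keep)


@dataclass
class SideEffectTable:
    """Protein-level side-effect association flags and per-drug adverse
    reaction counts."""

    protein_flags: dict[str, bool] = field(default_factory=dict)
    drug_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {d: c for d, c in self.drug_counts.items() if c < 0}
        if bad:
            raise ValueError(f"negative side-effect counts: {bad}")


# ---------------------------------------------------------------------------
# classification


def aggregate_max_pchembl(records: Iterable[ActivityRecord]) -> dict[tuple[str, str], float]:
    """Collapse repeated (drug, protein) measurements to the most potent one."""
    agg: dict[tuple[str, str], float] = {}
    for rec in records:
        key = (rec.drug_id, rec.protein_id)
        if key not in agg or rec.pchembl > agg[key]:
            agg[key] = rec.pchembl
    return agg


def classify_interactions(
    records: Iterable[ActivityRecord],
    target_min: float = 6.0,
    off_lo: float = 1.0,
    off_hi: float = 4.0,
) -> dict[tuple[str, str], InteractionClass]:
    """Classify aggregated (drug, protein) pairs into targets and off-targets.

    TARGET iff max pchembl >= target_min; OFF_TARGET iff off_lo <= pchembl
    <= off_hi; otherwise UNCLASSIFIED.  The (off_hi, target_min) gap is
    deliberately unclassified: the two affinity windows are disjoint queries,
    not a partition of the potency axis.
    """
    if not (target_min > off_hi >= off_lo >= 0):
        raise ValueError(
            f"inverted bounds: need target_min > off_hi >= off_lo >= 0, "
            f"got ({target_min}, {off_hi}, {off_lo})"
        )
    out: dict[tuple[str, str], InteractionClass] = {}
    for key, pchembl in aggregate_max_pchembl(records).items():
        if pchembl >= target_min:
            out[key] = InteractionClass.TARGET
        elif off_lo <= pchembl <= off_hi:
            out[key] = InteractionClass.OFF_TARGET
        else:
            out[key] = InteractionClass.UNCLASSIFIED
    return out


def build_profiles(
    interactions: Mapping[tuple[str, str], InteractionClass],
    family_table: FamilyTable,
) -> dict[str, DrugProfile]:
    """Assemble per-drug interaction profiles.

    Proteins absent from the family universe are logged and dropped.  Drugs
    whose classified interactions leave them with zero targets are retained
    (their family profile is empty) but flagged in the log.  Output is keyed
    and ordered by drug id for determinism.
    """
    targets: dict[str, set[str]] = {}
    off_targets: dict[str, set[str]] = {}
    dropped = 0
    for (drug, protein), cls in interactions.items():
        if protein not in family_table.universe:
            dropped += 1
            logger.debug("dropping %s: protein %s not in family universe", drug, protein)
            continue
        targets.setdefault(drug, set())
        off_targets.setdefault(drug, set())
        if cls is InteractionClass.TARGET:
            targets[drug].add(protein)
        elif cls is InteractionClass.OFF_TARGET:
            off_targets[drug].add(protein)
    if dropped:
        logger.info("build_profiles: dropped %d interactions outside the family universe", dropped)

    profiles: dict[str, DrugProfile] = {}
    for drug in sorted(targets):
        tset = frozenset(targets[drug])
        if not tset:
            logger.info("drug %s has no targets after classification", drug)
        fams = frozenset(
            f for f, rel in family_table.families.items() if rel & tset
        )
        profiles[drug] = DrugProfile(
            drug_id=drug,
            targets=tset,
            off_targets=frozenset(off_targets[drug]),
            family_profile=fams,
        )
    return profiles


# ---------------------------------------------------------------------------
# tabular IO

_ACTIVITY_COLS = ["drug_id", "protein_id", "pchembl_value"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a drug-protein activity TSV.

    Columns: drug_id, protein_id, pchembl_value[, therapeutic_flag,
    max_phase].  Malformed numeric fields raise ParseError naming the line
    (1-based, counting the header as line 1).
    """
    df = _read_tsv(path, _ACTIVITY_COLS)
    records: list[ActivityRecord] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            pchembl = float(row["pchembl_value"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: line {line_no}: non-numeric pchembl_value "
                f"{row['pchembl_value']!r}"
            ) from None
        if pchembl < 0:
            raise ParseError(f"{path}: line {line_no}: negative pchembl_value {pchembl}")
        therapeutic = None
        if "therapeutic_flag" in df.columns and pd.notna(row.get("therapeutic_flag")):
            therapeutic = row["therapeutic_flag"] in ("1", "true", "True")
        max_phase = None
        if "max_phase" in df.columns and pd.notna(row.get("max_phase")):
            try:
                max_phase = int(row["max_phase"])
            except ValueError:
                raise ParseError(
                    f"{path}: line {line_no}: non-integer max_phase {row['max_phase']!r}"
                ) from None
        records.append(
            ActivityRecord(
                drug_id=str(row["drug_id"]),
                protein_id=str(row["protein_id"]),
                pchembl=pchembl,
                therapeutic=therapeutic,
                max_phase=max_phase,
            )
        )
    return records


def write_activity_table(records: Iterable[ActivityRecord], path: str | Path) -> None:
    rows = [
        {
            "drug_id": r.drug_id,
            "protein_id": r.protein_id,
            "pchembl_value": r.pchembl,
            "therapeutic_flag": "" if r.therapeutic is None else int(r.therapeutic),
            "max_phase": "" if r.max_phase is None else r.max_phase,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_family_table(path: str | Path, universe: Iterable[str] | None = None) -> FamilyTable:
    """Read a family membership TSV (columns: family_id, protein_id)."""
    df = _read_tsv(path, ["family_id", "protein_id"])
    fams: dict[str, set[str]] = {}
    for idx, row in df.iterrows():
        if pd.isna(row["family_id"]) or pd.isna(row["protein_id"]):
            raise ParseError(f"{path}: line {int(idx) + 2}: empty family_id or protein_id")
        fams.setdefault(str(row["family_id"]), set()).add(str(row["protein_id"]))
    return FamilyTable(
        families={f: frozenset(m) for f, m in fams.items()},
        universe=frozenset(universe) if universe is not None else frozenset(),
    )


def write_family_table(table: FamilyTable, path: str | Path) -> None:
    rows = [
        {"family_id": f, "protein_id": p}
        for f in sorted(table.families)
        for p in sorted(table.families[f])
    ]
    pd.DataFrame(rows, columns=["family_id", "protein_id"]).to_csv(path, sep="\t", index=False)


def read_side_effects(
    protein_flags_path: str | Path | None = None,
    drug_counts_path: str | Path | None = None,
) -> SideEffectTable:
    """Read side-effect annotations.

    protein flags TSV: protein_id, associated (0/1); drug counts TSV:
    drug_id, n_side_effects (non-negative int).
    """
    flags: dict[str, bool] = {}
    counts: dict[str, int] = {}
    if protein_flags_path is not None:
        df = _read_tsv(protein_flags_path, ["protein_id", "associated"])
        for idx, row in df.iterrows():
            val = str(row["associated"]).strip()
            if val not in ("0", "1"):
                raise ParseError(
                    f"{protein_flags_path}: line {int(idx) + 2}: associated must be 0/1, got {val!r}"
                )
            flags[str(row["protein_id"])] = val == "1"
    if drug_counts_path is not None:
        df = _read_tsv(drug_counts_path, ["drug_id", "n_side_effects"])
        for idx, row in df.iterrows():
            try:
                n = int(row["n_side_effects"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{drug_counts_path}: line {int(idx) + 2}: non-integer "
                    f"n_side_effects {row['n_side_effects']!r}"
                ) from None
            if n < 0:
                raise ParseError(
                    f"{drug_counts_path}: line {int(idx) + 2}: negative n_side_effects {n}"
                )
            counts[str(row["drug_id"])] = n
    return SideEffectTable(protein_flags=flags, drug_counts=counts)


def write_side_effects(
    table: SideEffectTable,
    protein_flags_path: str | Path | None = None,
    drug_counts_path: str | Path | None = None,
) -> None:
    if protein_flags_path is not None:
        pd.DataFrame(
            [{"protein_id": p, "associated": int(v)} for p, v in sorted(table.protein_flags.items())],
            columns=["protein_id", "associated"],
        ).to_csv(protein_flags_path, sep="\t", index=False)
    if drug_counts_path is not None:
        pd.DataFrame(
            [{"drug_id": d, "n_side_effects": c} for d, c in sorted(table.drug_counts.items())],
            columns=["drug_id", "n_side_effects"],
        ).to_csv(drug_counts_path, sep="\t", index=False)


_ENRICHMENT_COLS = [
    "drug_id",
    "family_id",
    "n_ff",
    "p_ff",
    "success",
    "trials",
    "overrep_threshold",
    "p_value",
    "q_value",
    "significant",
]


def write_enrichment(records, path: str | Path) -> None:
    """Write enrichment records (see drugfams.enrichment.EnrichmentRecord)."""
    rows = [
        {
            "drug_id": r.drug_id,
            "family_id": r.family_id,
            "n_ff": r.n_ff,
            "p_ff": r.p_ff,
            "success": r.success,
            "trials": r.trials,
            "overrep_threshold": r.expected,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": int(r.significant),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ENRICHMENT_COLS).to_csv(path, sep="\t", index=False)


def read_enrichment(path: str | Path):
    from .enrichment import EnrichmentRecord

    df = _read_tsv(path, _ENRICHMENT_COLS)
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                EnrichmentRecord(
                    drug_id=str(row["drug_id"]),
                    family_id=str(row["family_id"]),
                    n_ff=int(row["n_ff"]),
                    p_ff=float(row["p_ff"]),
                    success=int(row["success"]),
                    trials=int(row["trials"]),
                    expected=float(row["overrep_threshold"]),
                    p_value=float(row["p_value"]),
                    q_value=float(row["q_value"]),
                    significant=bool(int(row["significant"])),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {int(idx) + 2}: {exc}") from None
    return out
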