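"""Shared independent oracles and worked-example fixtures."""

import math

from drugfams.core import DrugProfile, FamilyTable


def enum_binom_two_sided(success: int, trials: int, p: float) -> float:
    """Independent enumeration oracle: exact pmf via math.comb, summing all
    outcomes no more likely than the observed one (1e-7 relative slack)."""
    pmf = [math.comb(trials, k) * p**k * (1 - p) ** (trials - k) for k in range(trials + 1)]
    d = pmf[success]
    return min(1.0, sum(q for q in pmf if q <= d * (1 + 1e-7)))


def worked_example_tables():
    """A 25-protein universe, four families, and two drugs — one with 7
    targets concentrated in one family, one with 5 targets spread out."""
    proteins = [f"p{i}" for i in range(25)]
    fams = {
        "FF_1": frozenset(proteins[0:6]),     # n_ff 6
        "FF_2": frozenset(proteins[6:9]),     # n_ff 3
        "FF_3": frozenset(proteins[9:16]),    # n_ff 7
        "FF_4": frozenset(proteins[16:25]),   # n_ff 9
    }
    table = FamilyTable(families=fams, universe=frozenset(proteins))
    # 7 targets: 6 in FF_3, 1 in FF_2
    concentrated = DrugProfile(
        "drug_concentrated",
        targets=frozenset(proteins[9:15] + [proteins[6]]),
        off_targets=frozenset(),
        family_profile=frozenset({"FF_2", "FF_3"}),
    )
    # 5 targets spread: 1 in FF_1, 2 in FF_2, 1 in FF_3, 1 in FF_4
    spread = DrugProfile(
        "drug_spread",
        targets=frozenset([proteins[0], proteins[6], proteins[7], proteins[9], proteins[16]]),
        off_targets=frozenset(),
        family_profile=frozenset({"FF_1", "FF_2", "FF_3", "FF_4"}),
    )
    return table, concentrated, spread
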