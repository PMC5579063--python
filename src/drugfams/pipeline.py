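"""End-to-end orchestration: read inputs, run every stage in order
(enrichment -> similarity/SPP -> network statistics -> side-effect model),
write per-stage TSVs and a plain-text report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, enrichment, network as netmod, sidefx, similarity

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run.

    Stage toggles skip stages; a stage whose inputs are missing fails
    pre-flight with every problem listed at once.
    """

    activities: str | None = None
    families: str | None = None
    network: str | None = None
    fingerprints: str | None = None
    protein_side_effects: str | None = None
    drug_side_effects: str | None = None
    out_dir: str = "drugfams_out"

    target_min: float = 6.0
    off_lo: float = 1.0
    off_hi: float = 4.0
    q_threshold: float = 0.001
    universe: str = "all"
    adjust_scope: str = "batch"
    alpha: float = 0.005
    bin_width: float = 0.01
    score_scale: str = "unit"
    network_cutoff: float = 0.8
    n_random: int = 200
    neighbourhood_stat: str = "mean_pairwise"
    family_stat: str = "median_pairwise"
    seed: int = 0

    run_enrichment: bool = True
    run_spp: bool = True
    run_network: bool = True
    run_side_effects: bool = True

    def validate(self) -> None:
        problems = []
        needed = {"activities": self.activities, "families": self.families}
        if self.run_spp:
            needed["fingerprints"] = self.fingerprints
        if self.run_network or self.run_side_effects:
            needed["network"] = self.network
        if self.run_side_effects:
            needed["protein_side_effects"] = self.protein_side_effects
        for name, path in needed.items():
            if path is None:
                problems.append(f"missing input: {name}")
            elif not Path(path).is_file():
                problems.append(f"input file not found: {name} = {path}")
        if self.run_side_effects and not self.run_network:
            problems.append("side-effect stage needs the network stage (family scores)")
        if self.run_enrichment is False and self.run_network:
            problems.append("network stage needs enrichment (druggable family set)")
        if problems:
            raise ValueError("pre-flight failed:\n  " + "\n  ".join(problems))


def _checksum(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Run every enabled stage in order and write the report bundle.

    Returns a summary dict (also written as report.md / summary.json in the
    output directory).  Deterministic given the configured seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    summary: dict = {"seed": config.seed}

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["input_checksums"] = {
        k: _checksum(v)
        for k, v in cfg_dict.items()
        if k in ("activities", "families", "network", "fingerprints",
                 "protein_side_effects", "drug_side_effects")
        and v and Path(v).is_file()
    }
    (out / "config_echo.json").write_text(json.dumps(cfg_dict, indent=2))

    t0 = time.perf_counter()
    records = core.read_activity_table(config.activities)
    family_table = core.read_family_table(config.families)
    interactions = core.classify_interactions(
        records, config.target_min, config.off_lo, config.off_hi
    )
    profiles = core.build_profiles(interactions, family_table)
    summary["n_drugs"] = len(profiles)
    summary["n_families"] = len(family_table.families)
    summary["n_interactions"] = len(interactions)
    logger.info("inputs loaded in %.2fs: %d drugs, %d families",
                time.perf_counter() - t0, len(profiles), len(family_table.families))

    druggable: set[str] = set()
    if config.run_enrichment:
        t0 = time.perf_counter()
        enr_records, druggable = enrichment.run_enrichment(
            profiles,
            family_table,
            q_threshold=config.q_threshold,
            universe=config.universe,
            adjust_scope=config.adjust_scope,
        )
        core.write_enrichment(enr_records, out / "enrichment.tsv")
        summary["n_tests"] = len(enr_records)
        summary["n_significant_associations"] = sum(r.significant for r in enr_records)
        summary["n_druggable_families"] = len(druggable)
        summary["druggable_families"] = sorted(druggable)
        logger.info("enrichment: %d tests, %d significant, %d druggable families (%.2fs)",
                    len(enr_records), summary["n_significant_associations"],
                    len(druggable), time.perf_counter() - t0)

    if config.run_spp:
        t0 = time.perf_counter()
        fingerprints = similarity.read_fingerprints(config.fingerprints)
        spp_summary = {}
        for kind in ("protein", "family"):
            res = similarity.spp_analysis(
                profiles, fingerprints, profile_kind=kind,
                alpha=config.alpha, bin_width=config.bin_width,
            )
            pd.DataFrame(
                [{"tc_bin_lo": b.lo, "mean_jaccard": b.mean_jaccard, "n_pairs": b.n_pairs}
                 for b in res.bins]
            ).to_csv(out / f"spp_{kind}.tsv", sep="\t", index=False)
            spp_summary[kind] = {
                "tc_threshold": res.threshold,
                "mean_jaccard_above": res.mean_jaccard_above,
                "mean_jaccard_below": res.mean_jaccard_below,
                "n_pairs": res.n_pairs,
                "n_excluded_drugs": len(res.excluded_drugs),
            }
        summary["spp"] = spp_summary
        logger.info("spp done in %.2fs", time.perf_counter() - t0)

    family_scores_df = None
    if config.run_network:
        t0 = time.perf_counter()
        net = netmod.read_network(config.network, score_scale=config.score_scale)
        all_targets = sorted(
            {p for prof in profiles.values() for p in prof.targets} & net.nodes
        )
        cent = netmod.betweenness_analysis(
            all_targets, net, n_random=config.n_random, seed=rng,
            cutoff=config.network_cutoff,
        )
        summary["target_betweenness"] = dataclasses.asdict(cent)
        loc = netmod.localization(
            all_targets, net, n_random=min(config.n_random, 100), seed=rng,
            cutoff=config.network_cutoff, set_id="all_targets",
        )
        summary["target_localization"] = dataclasses.asdict(loc)

        nbh = netmod.drug_neighbourhood_table(
            profiles, net, n_random=1, seed=rng, kind=config.neighbourhood_stat
        )
        nbh.to_csv(out / "drug_neighbourhoods.tsv", sep="\t", index=False)
        summary["drug_neighbourhood_medians"] = {
            "target": float(nbh["target_score"].median()),
            "off_target": float(nbh["off_target_score"].median()),
            "random": float(nbh["random_score"].median()),
        }

        family_scores_df, comparison = netmod.family_neighbourhood(
            family_table, net, druggable=druggable if druggable else None,
            kind=config.family_stat,
        )
        family_scores_df.to_csv(out / "family_neighbourhoods.tsv", sep="\t", index=False)
        if comparison:
            summary["family_comparison"] = comparison
        logger.info("network stage done in %.2fs", time.perf_counter() - t0)

    if config.run_side_effects:
        t0 = time.perf_counter()
        se = core.read_side_effects(
            protein_flags_path=config.protein_side_effects,
            drug_counts_path=config.drug_side_effects,
        )
        labels = sidefx.label_families(family_table, se)
        scored = family_scores_df.dropna(subset=["score"])
        xs, ys = [], []
        for _, row in scored.iterrows():
            if row["family_id"] in labels:
                xs.append(float(row["score"]))
                ys.append(int(labels[row["family_id"]]))
        model = sidefx.fit_logistic(xs, ys)
        (out / "side_effect_model.txt").write_text(model.summary() + "\n")
        summary["logistic"] = {
            "beta0": model.beta0,
            "beta1": model.beta1,
            "threshold_star": model.threshold_star,
            "slope_pvalue": model.slope_pvalue,
            "p_free_at_zero": float(model.predict(0.0)),
            "n_obs": model.n_obs,
        }
        if se.drug_counts:
            nbh_scores = {
                row["drug_id"]: row["target_score"]
                for _, row in pd.read_csv(out / "drug_neighbourhoods.tsv", sep="\t").iterrows()
                if pd.notna(row["target_score"])
            }
            corr = sidefx.dispersion_sideeffect_correlation(nbh_scores, se.drug_counts)
            corr.pop("ids", None)
            summary["dispersion_sidefx_correlation"] = corr
        logger.info("side-effect stage done in %.2fs", time.perf_counter() - t0)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (out / "report.md").write_text(_render_report(summary))
    return summary


def _render_report(summary: dict) -> str:
    lines = ["# drugfams pipeline report", ""]
    lines.append(f"- drugs: {summary.get('n_drugs')}, families: {summary.get('n_families')}, "
                 f"aggregated interactions: {summary.get('n_interactions')}")
    if "n_tests" in summary:
        lines.append(
            f"- enrichment: {summary['n_tests']} (drug, family) tests, "
            f"{summary['n_significant_associations']} significant associations, "
            f"{summary['n_druggable_families']} druggable families"
        )
    if "spp" in summary:
        for kind, s in summary["spp"].items():
            lines.append(
                f"- SPP ({kind} profiles): Tc* = {s['tc_threshold']:.3f}; "
                f"mean Jaccard above/below = {s['mean_jaccard_above']:.3f} / "
                f"{s['mean_jaccard_below']:.3f} over {s['n_pairs']} pairs"
            )
    if "target_betweenness" in summary:
        c = summary["target_betweenness"]
        lines.append(
            f"- target betweenness: observed {c['observed']:.4g} vs null "
            f"{c['null_mean']:.4g} (z = {c['z_score']:.2f}, p = {c['empirical_p']:.4g})"
        )
    if "drug_neighbourhood_medians" in summary:
        m = summary["drug_neighbourhood_medians"]
        lines.append(
            f"- drug neighbourhood medians: targets {m['target']:.3f} > "
            f"off-targets {m['off_target']:.3f} > random {m['random']:.3f}"
        )
    if "family_comparison" in summary:
        fc = summary["family_comparison"]
        lines.append(
            f"- family neighbourhoods: druggable median {fc['median_druggable']:.3f} vs "
            f"rest {fc['median_rest']:.3f} (Mann-Whitney p = {fc['p_value']:.3g})"
        )
    if "logistic" in summary:
        lo = summary["logistic"]
        lines.append(
            f"- side-effect model: P(free|0) = {lo['p_free_at_zero']:.3f}, "
            f"0.5 threshold = {lo['threshold_star']:.3f} "
            f"(slope p = {lo['slope_pvalue']:.3g}, n = {lo['n_obs']})"
        )
    if "dispersion_sidefx_correlation" in summary:
        co = summary["dispersion_sidefx_correlation"]
        lines.append(
            f"- dispersion vs side-effect counts: Pearson r = {co['r']:.3f} "
            f"(p = {co['p_value']:.3g}, n = {co['n']})"
        )
    return "\n".join(lines) + "\n"
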