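"""End-to-end orchestration: simulate/load -> preprocess -> contrasts ->
classify -> enrich -> report, with a machine-readable run manifest.

A run is fully determined by its configuration and seed: re-running
with the same config reproduces every output byte-identically (wall
clock goes to the log, never into outputs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    CANONICAL_CONTRASTS,
    AbundanceTable,
    ContrastSpec,
    Treatment,
    ValidationError,
    read_abundance_tsv,
    read_annotation_tsv,
    write_abundance_tsv,
    write_results_tsv,
)
from .diffstats import pca, records_to_frame, run_contrasts
from .enrichment import bootstrap_proportion_test
from .grouping import (
    GROUPS,
    assignments_to_frame,
    classify_all,
    summarize,
)
from .preprocess import (
    filter_all_replicates,
    filter_min_fraction,
    impute_half_min,
    log2_transform,
    presence_mask,
    sum_over_timepoints,
)
from .simulate import GeneratorConfig, simulate_dataset, write_truth_tsv

logger = logging.getLogger(__name__)

PCA_TREATMENTS = ("N", "I", "C", "IC")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``generator`` (synthetic input) or ``abundance_path`` (and
    optionally ``annotation_path``) must be provided. All thresholds
    are parameters, never constants.
    """

    out_dir: str | Path = "run"
    generator: dict[str, Any] | None = None
    abundance_path: str | Path | None = None
    annotation_path: str | Path | None = None
    min_frac: float = 0.05
    contrasts: tuple[str, ...] = tuple(c.label for c in CANONICAL_CONTRASTS)
    alpha: float = 0.05
    use_adjusted: bool = False
    n_boot: int = 10_000
    enrichment_background: str = "differential"  # or "grouped"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.min_frac <= 1:
            raise ValidationError("min_frac must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.generator is None and self.abundance_path is None:
            raise ValidationError("provide a generator config or an abundance path")
        if self.abundance_path is not None and not Path(self.abundance_path).exists():
            raise ValidationError(f"abundance path {self.abundance_path} not found")
        if self.annotation_path is not None and not Path(self.annotation_path).exists():
            raise ValidationError(f"annotation path {self.annotation_path} not found")
        if self.enrichment_background not in ("differential", "grouped"):
            raise ValidationError(
                'enrichment_background must be "differential" or "grouped"'
            )
        for label in self.contrasts:
            parse_contrast(label)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)


def parse_contrast(label: str) -> ContrastSpec:
    """Parse 'TEST|REF' or 'TEST:REF' into a contrast."""
    for sep in ("|", ":"):
        if sep in label:
            test, ref = label.split(sep, 1)
            return ContrastSpec(Treatment.parse(test), Treatment.parse(ref))
    raise ValidationError(f"cannot parse contrast {label!r}; use TEST|REF")


@dataclass
class RunManifest:
    """Deterministic record of a run: config echo and stage counts."""

    config: dict[str, Any]
    version: str
    stages: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=2,
            sort_keys=True,
        )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order, writing stage outputs and a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_echo = dataclasses.asdict(config)
    cfg_echo["out_dir"] = str(config.out_dir)
    for key in ("abundance_path", "annotation_path"):
        if cfg_echo[key] is not None:
            cfg_echo[key] = str(cfg_echo[key])
    cfg_echo["contrasts"] = list(config.contrasts)
    manifest = RunManifest(config=cfg_echo, version=__version__)

    # -- input ------------------------------------------------------------
    annotation = None
    if config.generator is not None:
        gen_cfg = GeneratorConfig(**{**config.generator, "seed": config.seed})
        table, truth, annotation = simulate_dataset(gen_cfg)
        write_abundance_tsv(table, out / "abundance.tsv")
        write_truth_tsv(truth, out / "truth.tsv")
        annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    else:
        table = read_abundance_tsv(config.abundance_path)
    if config.annotation_path is not None:
        annotation = read_annotation_tsv(config.annotation_path)
    manifest.stages["input"] = {
        "n_proteins": len(table.proteins),
        "n_records": len(table),
        "n_missing": table.n_missing,
    }

    # -- preprocess -------------------------------------------------------
    filtered = filter_all_replicates(table)
    n_all_animals = len(filtered.proteins)
    filtered = filter_min_fraction(filtered, config.min_frac)
    mask = presence_mask(filtered)
    imputed = impute_half_min(filtered)
    summed = sum_over_timepoints(imputed)
    log2_table = log2_transform(imputed)
    manifest.stages["preprocess"] = {
        "n_after_all_replicates": n_all_animals,
        "n_after_min_fraction": len(filtered.proteins),
        "n_imputed_records": int(imputed.df["imputed"].sum()),
    }
    mask.to_csv(out / "presence_mask.tsv", sep="\t")
    summed.to_csv(out / "summed.tsv", sep="\t", float_format="%.10g")
    write_abundance_tsv(log2_table, out / "log2.tsv")

    # -- contrasts --------------------------------------------------------
    contrasts = [parse_contrast(label) for label in config.contrasts]
    records = run_contrasts(summed, contrasts)
    results_df = records_to_frame(records)
    write_results_tsv(results_df, out / "results.tsv")
    sig = results_df[results_df["p_adj" if config.use_adjusted else "p"] <= config.alpha]
    manifest.stages["contrasts"] = {
        "n_tests": len(results_df),
        "n_significant": int(len(sig)),
        "per_contrast_significant": {
            label: int((sig["contrast"] == label).sum())
            for label in config.contrasts
        },
    }

    # -- PCA --------------------------------------------------------------
    pca_result = _pca_on_log2(log2_table)
    pca_result.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(
        {
            "component": pca_result.scores.columns,
            "var_explained_pct": pca_result.var_explained,
        }
    ).to_csv(out / "pca_variance.tsv", sep="\t", index=False, float_format="%.10g")
    manifest.stages["pca"] = {
        "n_samples": len(pca_result.scores),
        "pc1_pct": round(float(pca_result.var_explained[0]), 4),
        "pc2_pct": round(float(pca_result.var_explained[1]), 4),
    }

    # -- classification ---------------------------------------------------
    assignments = classify_all(records, mask, config.alpha, config.use_adjusted)
    groups_df = assignments_to_frame(assignments)
    write_results_tsv(groups_df, out / "groups.tsv")
    summary = summarize(assignments)
    (out / "summary.json").write_text(
        json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True) + "\n"
    )
    manifest.stages["classify"] = {
        g: int((groups_df["group"] == g).sum()) for g in (*GROUPS, "none")
    }

    # -- enrichment -------------------------------------------------------
    enrichment_rows = []
    if annotation is not None:
        background = _background_proteins(
            results_df, assignments, config
        )
        seeds = np.random.SeedSequence(config.seed).spawn(len(GROUPS) * 2)
        k = 0
        for g in GROUPS:
            members = [a.protein_id for a in assignments if a.group == g]
            for category in ("intracellular", "extracellular"):
                seed_k = int(seeds[k].generate_state(1)[0] % (2**31))
                k += 1
                if not members:
                    continue
                res = bootstrap_proportion_test(
                    members,
                    background,
                    annotation,
                    category,
                    n_boot=config.n_boot,
                    seed=seed_k,
                    group_label=g,
                )
                enrichment_rows.append(dataclasses.asdict(res))
        if enrichment_rows:
            write_results_tsv(pd.DataFrame(enrichment_rows), out / "enrichment.tsv")
    manifest.stages["enrichment"] = {
        "n_tests": len(enrichment_rows),
        "annotation_provided": annotation is not None,
    }

    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    report_text = report(manifest, assignments, enrichment_rows)
    (out / "report.txt").write_text(report_text)
    return manifest


def _pca_on_log2(log2_table: AbundanceTable):
    """PCA over per-sample log2 profiles of the non-Dex core treatments.

    Samples (animal x treatment x day, treatments N/I/C/IC) are
    observations; proteins are variables.
    """
    df = log2_table.df
    df = df[df["treatment"].isin(PCA_TREATMENTS)]
    wide = df.pivot_table(
        index=["animal", "treatment", "day"],
        columns="protein",
        values="abundance",
    )
    wide.index = ["/".join(map(str, key)) for key in wide.index]
    constant = wide.std(axis=0, ddof=1) == 0
    if constant.any():
        logger.warning(
            "dropping %d zero-variance protein(s) before PCA", int(constant.sum())
        )
        wide = wide.loc[:, ~constant]
    return pca(wide)


def _background_proteins(results_df, assignments, config: RunConfig) -> list[str]:
    if config.enrichment_background == "grouped":
        return [a.protein_id for a in assignments if a.group in GROUPS]
    p_col = "p_adj" if config.use_adjusted else "p"
    vs_control = results_df[results_df["contrast"].isin(["C|N", "IC|N"])]
    sig = vs_control[vs_control[p_col] <= config.alpha]
    return sorted(sig["protein"].unique())


def report(manifest: RunManifest, assignments, enrichment_rows) -> str:
    """Plain-text run summary: group sizes, percentages, enrichment."""
    lines = [f"cartisec {manifest.version} run summary", ""]
    counts = manifest.stages.get("classify", {})
    grouped = [a for a in assignments if a.group in GROUPS]
    lines.append(
        "Groups: I={I} II={II} III={III} (none={none})".format(
            I=counts.get("I", 0),
            II=counts.get("II", 0),
            III=counts.get("III", 0),
            none=counts.get("none", 0),
        )
    )
    if grouped:
        s = summarize(assignments)
        lines.append(
            f"Increased release (II+III): {s.n_II + s.n_III} ({s.pct_increased}%)"
        )
        lines.append(f"Decreased release (I): {s.n_I} ({s.pct_decreased}%)")
        lines.append(
            f"Dex-decreased: {s.n_dex_decreased} ({s.pct_dex_decreased}%); "
            f"Dex-increased: {s.n_dex_increased} ({s.pct_dex_increased}%)"
        )
        lines.append(f"Group III reduced by Dex: {s.pct_III_dex_reduced}%")
    if enrichment_rows:
        lines.append("")
        lines.append("Localization enrichment (bootstrap):")
        for row in enrichment_rows:
            lines.append(
                "  group {group_label} {category}: {observed_prop:.2f} vs "
                "background {background_prop:.2f}, p={p_boot:.4g} ({tail})".format(
                    **row
                )
            )
    else:
        lines.append("")
        lines.append("Localization enrichment: omitted (no annotation provided)")
    return "\n".join(lines) + "\n"
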