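"""End-to-end orchestration: scan -> annotate -> profile -> associate.

:func:`run_pipeline` takes a genome, an exon annotation and a label file,
and writes a report bundle:

* ``hits.bed`` — all motif hits in genome coordinates (BED6+1);
* ``profiles.tsv`` — one row per (exon, region) with counts, proximal
  counts, intron length and maximum G-runs;
* ``table2_partial_correlations.tsv`` — partial Pearson correlation of
  occurrence count with skipping adjusting for intron length, per
  (structure, region);
* ``table3_proximal.tsv`` — skipped vs. constitutive proximal-presence
  comparison by one-sided two-sample proportion test;
* ``table4_logistic.tsv`` — the 12-predictor logistic model with Wald z;
* ``figure1_proportions.tsv`` — skipping proportion per occurrence-count
  stratum vs. the background probability;
* ``figure2_gruns.tsv`` — skipping proportion per maximum-G-run stratum,
  with the pooled G-run/skipping partial correlation in
  ``figure2_grun_partial.tsv``;
* ``run_log.txt`` — parameter echo, filter tallies and the background
  probability.

All stages are deterministic; re-running with the same inputs and config
produces byte-identical reports.
"""

from __future__ import annotations

import configparser
import dataclasses
import os
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    Region,
    background_probability,
    extract_flanking_introns,
    filter_entries,
    load_entries,
    profile_intron,
    profiles_to_frame,
)
from .scan import ScanParams, hits_to_bed_rows, scan_all
from .stats import (
    DegenerateStatisticError,
    SeparationError,
    STRUCTURE_COLUMNS,
    add_bh_column,
    build_design_matrix,
    fit_logistic,
    g_run_association,
    group_proportions,
    partial_pearson,
    proximal_comparison,
    significance_stars,
)

__all__ = [
    "AnalysisConfig",
    "PipelineError",
    "ConfigError",
    "InputError",
    "StatsError",
    "run_pipeline",
    "summarize",
    "REPORT_FILES",
]

REPORT_FILES = (
    "table2_partial_correlations.tsv",
    "table3_proximal.tsv",
    "table4_logistic.tsv",
    "figure1_proportions.tsv",
    "figure2_gruns.tsv",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ConfigError(PipelineError):
    pass


class InputError(PipelineError):
    pass


class StatsError(PipelineError):
    pass


@dataclass
class AnalysisConfig:
    genome: str = ""
    annotation: str = ""
    labels: str = ""
    out_dir: str = "results"
    scan_params: ScanParams = field(default_factory=ScanParams)
    window: int = 500
    one_sided: bool = True
    benjamini_hochberg: bool = True
    merge_g4_strands: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")

    @classmethod
    def from_ini(cls, path: str) -> "AnalysisConfig":
        if not os.path.exists(path):
            raise ConfigError("config", f"config file not found: {path}")
        parser = configparser.ConfigParser()
        parser.read(path)
        kwargs = {}
        scan_kwargs = {}
        scan_fields = {f.name: f.type for f in dataclasses.fields(ScanParams)}
        section = parser["analysis"] if parser.has_section("analysis") else {}
        for key, value in dict(section).items():
            if key in ("genome", "annotation", "labels", "out_dir"):
                kwargs[key] = value
            elif key in ("window", "seed"):
                kwargs[key] = int(value)
            elif key in ("one_sided", "benjamini_hochberg", "merge_g4_strands"):
                kwargs[key] = value.strip().lower() in ("1", "true", "yes")
            else:
                raise ConfigError("config", f"unknown analysis option {key!r}")
        if parser.has_section("scan"):
            for key, value in parser["scan"].items():
                if key not in scan_fields:
                    raise ConfigError("config", f"unknown scan option {key!r}")
                if key == "z_allowed_dinucleotides":
                    scan_kwargs[key] = frozenset(
                        v.strip().upper() for v in value.split(",")
                    )
                elif key == "triplex_min_purity":
                    scan_kwargs[key] = float(value)
                else:
                    scan_kwargs[key] = int(value)
        try:
            params = ScanParams(**scan_kwargs)
        except ValueError as exc:
            raise ConfigError("config", str(exc)) from exc
        return cls(scan_params=params, **kwargs)


def _check_inputs(config: AnalysisConfig) -> None:
    for name in ("genome", "annotation", "labels"):
        path = getattr(config, name)
        if not path:
            raise ConfigError("config", f"missing required path: {name}")
        if not os.path.exists(path):
            raise ConfigError("config", f"{name} file not found: {path}")


def run_pipeline(config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the report bundle to
    ``config.out_dir``; returns the report tables in memory."""
    import pyfaidx

    _check_inputs(config)
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines = [f"nonbsplice {__version__}"]
    log_lines.append("[config]")
    for name in ("genome", "annotation", "labels", "out_dir", "window",
                 "one_sided", "benjamini_hochberg", "merge_g4_strands", "seed"):
        log_lines.append(f"{name}\t{getattr(config, name)}")
    for f in dataclasses.fields(ScanParams):
        value = getattr(config.scan_params, f.name)
        if isinstance(value, frozenset):
            value = ",".join(sorted(value))
        log_lines.append(f"scan.{f.name}\t{value}")

    # --- load & filter ----------------------------------------------------
    try:
        entries = load_entries(config.annotation, config.labels)
    except (ValueError, KeyError, OSError) as exc:
        raise InputError("load", str(exc)) from exc
    retained, fstats = filter_entries(entries)
    log_lines.append("[filters]")
    log_lines.append(f"entries_input\t{fstats.n_input}")
    log_lines.append(f"duplicates_collapsed\t{fstats.n_duplicates_collapsed}")
    log_lines.append(f"overlap_removed\t{fstats.n_overlap_removed}")
    log_lines.append(f"many_exon_removed\t{fstats.n_many_exon_removed}")
    log_lines.append(f"entries_retained\t{fstats.n_retained}")

    # --- extract & profile ------------------------------------------------
    try:
        genome = pyfaidx.Fasta(config.genome)
    except Exception as exc:
        raise InputError("genome", str(exc)) from exc
    records = []
    for entry in retained:
        if entry.label is None:
            raise InputError(
                "annotate", f"entry {entry.entry_id} has no label"
            )
        try:
            records.extend(extract_flanking_introns(entry, genome))
        except ValueError as exc:
            raise InputError("annotate", str(exc)) from exc
    if not records:
        raise InputError("annotate", "no eligible exons (internal exons with "
                         "both flanking introns)")
    bed_rows = []
    profile_rows = []
    n_triplex_ppt_removed = 0
    n_cross_class_removed = 0
    for rec in records:
        for region, seq, interval in (
            (Region.UPSTREAM, rec.upstream_seq, rec.upstream_intron),
            (Region.DOWNSTREAM, rec.downstream_seq, rec.downstream_intron),
        ):
            hits = scan_all(seq, config.scan_params)
            prof = profile_intron(
                seq, region, config.scan_params, config.window,
                rec.entry_id, _hits=hits,
            )
            n_triplex_ppt_removed += prof.n_triplex_removed_ppt
            profile_rows.append((rec, prof))
            if rec.orientation.value == "+":
                offset, gstrand = interval[0], "+"
            else:
                offset, gstrand = interval[1], "-"
            for cls_hits in hits.values():
                bed_rows.extend(
                    hits_to_bed_rows(cls_hits, rec.chrom, offset, gstrand)
                )
    profiles = profiles_to_frame(profile_rows)
    background = background_probability(records)
    log_lines.append("[data]")
    log_lines.append(f"eligible_exons\t{len(records)}")
    log_lines.append(f"background_probability\t{background:.6g}")
    log_lines.append(f"triplex_removed_ppt\t{n_triplex_ppt_removed}")

    with open(os.path.join(config.out_dir, "hits.bed"), "w") as fh:
        fh.write("\n".join(bed_rows) + ("\n" if bed_rows else ""))
    profiles.to_csv(
        os.path.join(config.out_dir, "profiles.tsv"), sep="\t", index=False
    )

    # --- statistics -------------------------------------------------------
    reports: dict[str, pd.DataFrame] = {}
    try:
        reports["table2_partial_correlations"] = _partial_correlation_table(
            profiles, config
        )
        reports["table3_proximal"] = _proximal_table(profiles, config)
        reports["table4_logistic"] = _logistic_table(profiles, config)
        reports["figure1_proportions"] = group_proportions(
            profiles, background, "count"
        )
        fig2, grun_corr = _g_run_tables(profiles, background)
        reports["figure2_gruns"] = fig2
        reports["figure2_grun_partial"] = grun_corr
    except (ValueError, DegenerateStatisticError, SeparationError) as exc:
        raise StatsError("associate", str(exc)) from exc

    for name, table in reports.items():
        table.to_csv(
            os.path.join(config.out_dir, f"{name}.tsv"), sep="\t", index=False
        )
    with open(os.path.join(config.out_dir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return reports


def _partial_correlation_table(
    profiles: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    alternative = "greater" if config.one_sided else "two-sided"
    rows = []
    for region in ("upstream", "downstream"):
        reg = profiles[profiles["region"] == region]
        y = (reg["label"] == "SKIPPED").to_numpy(dtype=float)
        z = reg["intron_length"].to_numpy(dtype=float)
        for structure in STRUCTURE_COLUMNS:
            x = reg[f"n_{structure}"].to_numpy(dtype=float)
            try:
                res = partial_pearson(x, y, z, alternative=alternative)
                r, t, p, n = res.r, res.t_stat, res.p_value, res.n
            except (DegenerateStatisticError, ValueError):
                r = t = p = np.nan
                n = len(reg)
            rows.append(
                {
                    "region": region,
                    "structure": structure,
                    "r": r,
                    "t_stat": t,
                    "n": n,
                    "p_value": p,
                    "stars": significance_stars(p) if np.isfinite(p) else "",
                }
            )
    table = pd.DataFrame(rows)
    if config.benjamini_hochberg:
        table = add_bh_column(table)
    return table


def _proximal_table(
    profiles: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    alternative = "greater" if config.one_sided else "two-sided"
    table = proximal_comparison(profiles, alternative=alternative)
    table["stars"] = [
        significance_stars(p) if np.isfinite(p) else ""
        for p in table["p_value"]
    ]
    if config.benjamini_hochberg:
        table = add_bh_column(table)
    return table


def _logistic_table(
    profiles: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    X, y = build_design_matrix(profiles, merge_g4_strands=config.merge_g4_strands)
    fit = fit_logistic(X, y)
    table = fit.summary_frame().reset_index(names="predictor")
    table["stars"] = [significance_stars(p) for p in table["p_value"]]
    if config.benjamini_hochberg:
        table = add_bh_column(table)
    return table


def _g_run_tables(
    profiles: pd.DataFrame, background: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    has_g4 = (
        (profiles["max_g_run_template"] > 0)
        | (profiles["max_g_run_nontemplate"] > 0)
    ).any()
    if not has_g4:
        empty = group_proportions(profiles, background, "g_run")
        corr = pd.DataFrame(
            [{"r": np.nan, "t_stat": np.nan, "df": np.nan, "p_value": np.nan,
              "n": 0, "note": "no G4-bearing introns"}]
        )
        return empty, corr
    try:
        table, corr = g_run_association(profiles, background)
        corr_frame = pd.DataFrame(
            [{"r": corr.r, "t_stat": corr.t_stat, "df": corr.df,
              "p_value": corr.p_value, "n": corr.n, "note": ""}]
        )
    except DegenerateStatisticError as exc:
        table = group_proportions(profiles, background, "g_run")
        corr_frame = pd.DataFrame(
            [{"r": np.nan, "t_stat": np.nan, "df": np.nan, "p_value": np.nan,
              "n": 0, "note": str(exc)}]
        )
    return table, corr_frame


# ---------------------------------------------------------------------------
# summary

def summarize(report_dir: str) -> str:
    """Human-readable digest of a report bundle: background probability,
    configured window and per-(structure, region) significance stars."""
    log_path = os.path.join(report_dir, "run_log.txt")
    if not os.path.exists(log_path):
        raise InputError("summarize", f"missing report file: {log_path}")
    meta = {}
    for line in open(log_path):
        if "\t" in line:
            key, value = line.rstrip("\n").split("\t", 1)
            meta[key] = value
    lines = [f"nonbsplice summary of {report_dir}"]
    n_exons = int(meta.get("eligible_exons", 0))
    if n_exons == 0:
        lines.append("no eligible exons")
        return "\n".join(lines)
    lines.append(f"eligible exons: {n_exons}")
    lines.append(
        f"background skipping probability: {meta.get('background_probability')}"
    )
    lines.append(f"proximal window: {meta.get('window')} nt")
    t2_path = os.path.join(report_dir, "table2_partial_correlations.tsv")
    if not os.path.exists(t2_path):
        raise InputError("summarize", f"missing report file: {t2_path}")
    t2 = pd.read_csv(t2_path, sep="\t")
    lines.append(
        "partial correlation with skipping, adjusted for intron length "
        "(* P<0.01, ** P<0.001, *** P<0.0001):"
    )
    for _, row in t2.iterrows():
        stars = row["stars"] if isinstance(row["stars"], str) else ""
        r = "NA" if pd.isna(row["r"]) else f"{row['r']:+.4f}"
        p = "NA" if pd.isna(row["p_value"]) else f"{row['p_value']:.3g}"
        lines.append(
            f"  {row['region']:>10} {row['structure']:<16} r={r} "
            f"P={p} {stars}"
        )
    return "\n".join(lines)
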