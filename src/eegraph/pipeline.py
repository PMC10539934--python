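"""End-to-end orchestration: cohort in, per-family feature tables and group
statistics out, with a reproducibility manifest.

Stage order per subject: preprocess -> spectral -> complexity -> connectivity
-> graph -> stats.  All randomized stages draw independent child seeds from
the master seed, so partial re-runs stay reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .complexity import multiscale_curve
from .connectivity import connectivity_matrix, region_mean, whole_brain_mean
from .montage import CHANNELS, REGIONS
from .preprocess import EpochSet, Recording, preprocess_recording
from .spectral import BAND_BY_NAME, CANONICAL_BANDS, band_power, multitaper_psd
from .graph import binarize_top_n, nodal_efficiencies, sparsity_sweep
from .stats import (
    ComparisonResult,
    bootstrap_ci,
    fdr_scheme,
    normality_gate_compare,
    wilcoxon_rank_sum,
)
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "report_summary"]

RESULT_TABLES = (
    "band_power.tsv",
    "band_power_stats.tsv",
    "entropy.tsv",
    "entropy_stats.tsv",
    "connectivity.tsv",
    "connectivity_stats.tsv",
    "region_stats.tsv",
    "graph_sweep.tsv",
    "graph_sweep_stats.tsv",
    "nodal_efficiency_stats.tsv",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    cohort: CohortSpec | None = None
    edf_dir: str | None = None
    roster: str | None = None  # TSV: subject_id <tab> group <tab> filename
    out_dir: str = "eegraph_out"
    # preprocessing
    f_lo: float = 0.1
    f_hi: float = 50.0
    epoch_length: float = 2.0
    n_keep: int = 50
    amp_limit: float = 150.0
    flat_limit: float = 0.5
    # spectral / complexity
    bands: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
    entropy_scales: tuple[int, ...] = tuple(range(1, 31))
    entropy_report_scale: int = 4
    sample_m: int = 1
    sample_r: float = 0.25
    perm_m: int = 3
    # connectivity / graph
    wpli_per_epoch: bool = False
    efficiency_grid: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.701, 0.01), 2))
    sigma_grid: tuple[float, ...] = tuple(np.round(np.arange(0.70, 0.851, 0.01), 2))
    nodal_sparsity: float = 0.20
    n_refs: int = 100
    # stats
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = CohortSpec.from_dict(raw["cohort"])
        for key in ("bands", "entropy_scales", "efficiency_grid", "sigma_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        return d


def _load_cohort(cfg: RunConfig) -> list[Recording]:
    if cfg.cohort is not None:
        return generate_cohort(cfg.cohort)
    if cfg.edf_dir is None or cfg.roster is None:
        raise ValueError("config needs either a cohort spec or edf_dir + roster")
    from .io_edf import read_edf

    recs = []
    roster = pd.read_csv(cfg.roster, sep="\t", header=None,
                         names=["subject_id", "group", "filename"])
    for row in roster.itertuples():
        recs.append(read_edf(Path(cfg.edf_dir) / row.filename,
                             subject_id=str(row.subject_id), group=row.group))
    return recs


def _compare_groups(
    df: pd.DataFrame, value_col: str, feature_cols: Sequence[str], scheme: str,
) -> pd.DataFrame:
    """Wilcoxon rank-sum per feature cell, then the family FDR scheme."""
    results: list[ComparisonResult] = []
    for keys, sub in df.groupby(list(feature_cols), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        a = sub.loc[sub["group"] == "HC", value_col].to_numpy()
        b = sub.loc[sub["group"] == "MCI", value_col].to_numpy()
        stat, p = wilcoxon_rank_sum(a, b)
        feat = dict(zip(feature_cols, keys))
        results.append(ComparisonResult(
            feature=feat, test="wilcoxon", statistic=stat, p_raw=p,
            summary_a=f"{np.median(a):.6g}", summary_b=f"{np.median(b):.6g}",
        ))
    results = fdr_scheme(results, scheme)
    rows = []
    for r in results:
        row = dict(r.feature)
        row.update(statistic=r.statistic, p_raw=r.p_raw,
                   p_fdr=r.p_fdr if r.p_fdr is not None else np.nan,
                   median_hc=r.summary_a, median_mci=r.summary_b)
        rows.append(row)
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write all result tables plus a manifest.

    Returns the manifest dict.  Identical (config, seed) reproduce identical
    tables byte for byte.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    master = np.random.default_rng(cfg.seed)
    seeds = {name: int(master.integers(0, 2**31 - 1))
             for name in ("sigma", "bootstrap")}
    bands = [BAND_BY_NAME[b] for b in cfg.bands]
    checksums: dict[str, str] = {}

    recs = _load_cohort(cfg)
    epochsets: list[EpochSet] = []
    for rec in recs:
        try:
            epochsets.append(preprocess_recording(
                rec, cfg.f_lo, cfg.f_hi, cfg.epoch_length, cfg.n_keep,
                cfg.amp_limit, cfg.flat_limit))
        except Exception as exc:
            raise RuntimeError(
                f"stage 'preprocess' failed for subject {rec.subject_id!r}: {exc}"
            ) from exc

    # ---- spectral -----------------------------------------------------
    rows = []
    for es in epochsets:
        psd = multitaper_psd(es)
        for band in bands:
            for ch, val in zip(es.channels, band_power(psd, band)):
                rows.append((es.subject_id, es.group, ch, band.name, val))
    bp = pd.DataFrame(rows, columns=["subject", "group", "channel", "band", "power"])
    checksums["band_power.tsv"] = _write(bp, out / "band_power.tsv")
    bp_stats = _compare_groups(bp, "power", ["band", "channel"],
                               "per_band_across_electrodes")
    checksums["band_power_stats.tsv"] = _write(bp_stats, out / "band_power_stats.tsv")

    # ---- complexity ---------------------------------------------------
    rows = []
    for es in epochsets:
        concat = es.concatenated()
        for ci, ch in enumerate(es.channels):
            for est, m in (("sample", cfg.sample_m), ("permutation", cfg.perm_m)):
                curve = multiscale_curve(
                    concat[ci], est, cfg.entropy_scales, m=m, r=cfg.sample_r,
                    channel=ch, subject_id=es.subject_id)
                for tau, v in zip(curve.scales, curve.values):
                    rows.append((es.subject_id, es.group, ch, est, tau, v))
    ent = pd.DataFrame(rows, columns=["subject", "group", "channel",
                                      "estimator", "scale", "value"])
    checksums["entropy.tsv"] = _write(ent, out / "entropy.tsv")
    ent_at = ent[ent["scale"] == cfg.entropy_report_scale]
    if ent_at.empty:
        ent_at = ent[ent["scale"] == ent["scale"].max()]
    ent_stats = _compare_groups(
        ent_at.rename(columns={"estimator": "band"}), "value",
        ["band", "channel"], "per_band_across_electrodes")
    ent_stats = ent_stats.rename(columns={"band": "estimator"})
    checksums["entropy_stats.tsv"] = _write(ent_stats, out / "entropy_stats.tsv")

    # ---- connectivity -------------------------------------------------
    matrices: dict[tuple[str, str], object] = {}
    rows = []
    region_rows = []
    region_names = list(REGIONS)
    for es in epochsets:
        for band in bands:
            cm = connectivity_matrix(es, band, per_epoch=cfg.wpli_per_epoch)
            matrices[(es.subject_id, band.name)] = cm
            iu = np.triu_indices(len(cm.channels), k=1)
            for i, j in zip(*iu):
                rows.append((band.name, cm.channels[i], cm.channels[j],
                             es.subject_id, es.group, cm.values[i, j]))
            for ai, ra in enumerate(region_names):
                for rb in region_names[ai:]:
                    region_rows.append((band.name, ra, rb, es.subject_id,
                                        es.group, region_mean(cm, ra, rb)))
            rows.append((band.name, "WHOLE", "BRAIN", es.subject_id, es.group,
                         whole_brain_mean(cm)))
    conn = pd.DataFrame(rows, columns=["band", "chan_i", "chan_j",
                                       "subject", "group", "wpli"])
    checksums["connectivity.tsv"] = _write(conn, out / "connectivity.tsv")
    pairs = conn[conn["chan_i"] != "WHOLE"].copy()
    pairs["pair"] = pairs["chan_i"] + "-" + pairs["chan_j"]
    conn_stats = _compare_groups(pairs, "wpli", ["pair", "band"],
                                 "per_connection_across_bands")
    checksums["connectivity_stats.tsv"] = _write(conn_stats, out / "connectivity_stats.tsv")
    reg = pd.DataFrame(region_rows, columns=["band", "region_a", "region_b",
                                             "subject", "group", "wpli"])
    reg["pair"] = reg["region_a"] + "-" + reg["region_b"]
    reg_stats = _compare_groups(reg, "wpli", ["pair", "band"],
                                "per_connection_across_bands")
    checksums["region_stats.tsv"] = _write(reg_stats, out / "region_stats.tsv")

    # ---- graph --------------------------------------------------------
    sweep_rows = []
    nodal_rows = []
    sigma_rng = np.random.default_rng(seeds["sigma"])
    for es in epochsets:
        for band in bands:
            cm = matrices[(es.subject_id, band.name)]
            sw = sparsity_sweep(cm, cfg.efficiency_grid)
            for m in sw.metrics:
                sweep_rows.append((band.name, m.sparsity, es.subject_id, es.group,
                                   "e_glob", m.e_glob))
                sweep_rows.append((band.name, m.sparsity, es.subject_id, es.group,
                                   "e_loc", m.e_loc))
            sg = sparsity_sweep(cm, cfg.sigma_grid, with_sigma=True,
                                n_refs=cfg.n_refs,
                                seed=int(sigma_rng.integers(0, 2**31 - 1)))
            for m in sg.metrics:
                sweep_rows.append((band.name, m.sparsity, es.subject_id, es.group,
                                   "sigma", m.sigma))
            g = binarize_top_n(cm, cfg.nodal_sparsity)
            for ch, ne in zip(cm.channels, nodal_efficiencies(g)):
                nodal_rows.append((band.name, ch, es.subject_id, es.group, ne))
    sweep = pd.DataFrame(sweep_rows, columns=["band", "sparsity", "subject",
                                              "group", "metric", "value"])
    checksums["graph_sweep.tsv"] = _write(sweep, out / "graph_sweep.tsv")
    # per-point tests, no cross-point correction (reported uncorrected)
    sweep_stats = _compare_groups(sweep, "value", ["metric", "band", "sparsity"],
                                  "none")
    checksums["graph_sweep_stats.tsv"] = _write(sweep_stats, out / "graph_sweep_stats.tsv")
    nodal = pd.DataFrame(nodal_rows, columns=["band", "channel", "subject",
                                              "group", "value"])
    nodal_stats = _compare_groups(nodal, "value", ["band", "channel"],
                                  "per_band_across_electrodes")
    checksums["nodal_efficiency_stats.tsv"] = _write(
        nodal_stats, out / "nodal_efficiency_stats.tsv")

    # ---- bootstrap CIs on group entropy means -------------------------
    boot_rng = np.random.default_rng(seeds["bootstrap"])
    ci_rows = []
    for (est, tau, grp), sub in ent.groupby(["estimator", "scale", "group"], sort=True):
        channel_mean = sub.groupby("subject", sort=True)["value"].mean().to_numpy()
        lo, hi = bootstrap_ci(channel_mean, n_boot=cfg.n_boot,
                              seed=int(boot_rng.integers(0, 2**31 - 1)))
        ci_rows.append((est, tau, grp, channel_mean.mean(), lo, hi))
    ci = pd.DataFrame(ci_rows, columns=["estimator", "scale", "group",
                                        "mean", "ci_lo", "ci_hi"])
    checksums["entropy_group_ci.tsv"] = _write(ci, out / "entropy_group_ci.tsv")

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seeds": {"master": cfg.seed, **seeds},
        "n_subjects": len(epochsets),
        "checksums": checksums,
        "wall_time_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def report_summary(out_dir, alpha: float = 0.05) -> str:
    """Digest of significant findings per analysis family.

    Families corrected by FDR report rows with ``p_fdr < alpha``; the
    uncorrected sweep families report raw ``p < alpha``.
    """
    out = Path(out_dir)
    sections = []
    spec = [
        ("Spectral band power", "band_power_stats.tsv", "p_fdr",
         ["band", "channel"]),
        ("Multiscale entropy", "entropy_stats.tsv", "p_fdr",
         ["estimator", "channel"]),
        ("wPLI connections", "connectivity_stats.tsv", "p_fdr",
         ["band", "pair"]),
        ("Regional wPLI", "region_stats.tsv", "p_fdr", ["band", "pair"]),
        ("Nodal efficiency", "nodal_efficiency_stats.tsv", "p_fdr",
         ["band", "channel"]),
        ("Efficiency / small-world sweeps (uncorrected)",
         "graph_sweep_stats.tsv", "p_raw", ["metric", "band", "sparsity"]),
    ]
    for title, fname, pcol, keys in spec:
        path = out / fname
        if not path.exists():
            raise FileNotFoundError(f"missing result table {fname}")
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in keys + [pcol, "median_hc", "median_mci"]
                   if c not in df.columns]
        if missing:
            raise ValueError(f"table {fname} lacks columns {missing}")
        sig = df[df[pcol] < alpha]
        lines = [f"== {title}: {len(sig)} significant =="]
        for row in sig.itertuples():
            label = " ".join(str(getattr(row, k)) for k in keys)
            direction = ("HC > MCI"
                         if float(row.median_hc) > float(row.median_mci)
                         else "MCI > HC")
            lines.append(f"  {label}: {pcol}={getattr(row, pcol):.4g} ({direction})")
        sections.append("\n".join(lines))
    return "\n".join(sections) + "\n"
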