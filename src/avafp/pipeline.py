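"""End-to-end analysis: recordings -> avalanches -> ATMs -> fingerprints,
stability and statistics.

``analyze_cohort`` holds the in-memory pipeline the tests exercise;
``run_pipeline`` wraps it with file output and a reproducibility log.  Stage
order: per subject-session z-score, threshold, bin-scale selection by the
branching ratio, avalanche segmentation, ATM; per group identifiability and
edge ICC; globally the omnibus/post-hoc permutation statistics with BH-FDR,
the clinical-fingerprint correlation, and the cross-validated regression.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import stats as st
from .atm import TransitionMatrix, recording_atm
from .avalanche import (
    BinaryRaster,
    Recording,
    _sigma_from_counts,
    binarize,
    coarse_grain,
    detect_avalanches,
    select_scale,
    select_window,
    zscore_series,
)
from .fingerprint import fingerprint_scores, iclinical, identifiability_matrix
from .io import write_manifest, write_matrix
from .stability import edge_icc, group_mean_stability, node_stability
from .synthgen import CohortSpec, iter_cohort

log = logging.getLogger("avafp")

__all__ = ["PipelineConfig", "CohortResults", "process_recording",
           "analyze_cohort", "run_pipeline"]

DISPLAY_GROUPS = ("HC", "UTLE-L", "UTLE-R", "BTLE")


@dataclass
class PipelineConfig:
    """Tunables of the analysis stage (defaults = study conditions)."""

    threshold: float = 2.8          # SD units; robustness variants: 2.6, 3.0
    use_s: float = 100.0            # analyzed window per session (s); 180 = whole trial
    delta_bins: int = 1             # ATM lag in bins
    # bin-scale policy: "cohort" picks one scale for the whole dataset by the
    # pooled |sigma - 1|; "recording" selects per recording; an int forces it
    scale_selection: str | int = "cohort"
    n_perm: int = 10_000
    k_folds: int = 5
    n_iter: int = 4000              # CV iterations for the regression
    seed: int = 0


@dataclass
class CohortResults:
    """Everything the analysis computes, in memory."""

    atms: dict[str, tuple[TransitionMatrix, TransitionMatrix]]
    manifest: pd.DataFrame
    sigma: pd.DataFrame
    fingerprints: pd.DataFrame
    identifiability: dict[str, Any]
    stability: dict[str, Any]
    omnibus: pd.DataFrame
    posthoc: pd.DataFrame
    iclinical: pd.Series
    clinical_correlations: pd.DataFrame | None = None
    regression: st.RegressionReport | None = None


def _sigma_by_scale(raster: BinaryRaster) -> dict[int, float]:
    """sigma at bin scales 1, 2, 3 straight from active-count series."""
    out = {}
    for k in (1, 2, 3):
        r = raster if k == 1 else coarse_grain(raster, k)
        out[k] = _sigma_from_counts(r.data.sum(axis=0))[0]
    return out


def _make_raster(rec: Recording, cfg: PipelineConfig, rng: np.random.Generator):
    if cfg.use_s < rec.duration_s:
        rec = select_window(rec, cfg.use_s, rng)
    return binarize(zscore_series(rec), cfg.threshold)


def _atm_at_scale(
    raster: BinaryRaster,
    scale: int,
    cfg: PipelineConfig,
    roi_names,
) -> tuple[TransitionMatrix, int]:
    chosen = raster if scale == 1 else coarse_grain(raster, scale)
    avalanches = detect_avalanches(chosen)
    atm = recording_atm(avalanches, delta_bins=cfg.delta_bins, roi_names=roi_names)
    return atm, len(avalanches)


def process_recording(
    rec: Recording, cfg: PipelineConfig, rng: np.random.Generator
) -> tuple[TransitionMatrix, dict[str, Any]]:
    """One subject-session: window, z-score, binarize, scale-select, ATM.

    Stand-alone form with per-recording scale selection (or a forced integer
    scale); the cohort pipeline instead pools sigma across recordings first.
    """
    if cfg.use_s < rec.duration_s:
        rec = select_window(rec, cfg.use_s, rng)
    z = zscore_series(rec)
    raster = binarize(z, cfg.threshold)
    if isinstance(cfg.scale_selection, int):
        scale = cfg.scale_selection
        sigmas = _sigma_by_scale(raster)
    else:
        scale, estimates = select_scale(raster)
        sigmas = {k: est.sigma for k, est in estimates.items()}
    atm, n_av = _atm_at_scale(raster, scale, cfg, rec.roi_names)
    info = {
        "subject_id": rec.subject_id,
        "session": rec.session,
        "group": rec.group,
        "scale": scale,
        "n_avalanches": n_av,
        "n_short_excluded": atm.n_short,
        **{f"sigma_scale{k}": s for k, s in sigmas.items()},
    }
    return atm, info


def process_cohort(
    spec: CohortSpec, cfg: PipelineConfig
) -> tuple[dict[str, tuple[TransitionMatrix, TransitionMatrix]], pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and compute per-session ATMs at a common bin scale.

    Pass one streams the cohort, keeps each session's binary raster and its
    sigma at scales 1-3; the scale whose geometric-mean sigma across all
    recordings is closest to 1 is then applied uniformly (ties to the smaller
    scale), so every ATM lives on the same time base.  Returns (atms,
    manifest, sigma table).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA7A]))
    rasters: list[tuple[str, str, BinaryRaster]] = []
    rows, info_rows = [], []
    roi_names = None
    for row, rec_t, rec_r in iter_cohort(spec):
        sid = row["subject_id"]
        roi_names = rec_t.roi_names
        for rec in (rec_t, rec_r):
            raster = _make_raster(rec, cfg, rng)
            info = {
                "subject_id": sid,
                "session": rec.session,
                "group": rec.group,
                **{f"sigma_scale{k}": s for k, s in _sigma_by_scale(raster).items()},
            }
            info_rows.append(info)
            rasters.append((sid, rec.session, raster))
        rows.append(
            {k: v for k, v in row.items()
             if k not in ("kernel", "session_kernels", "w_s",
                          "rocft_recall_signal", "template_similarity")}
        )
    sigma = pd.DataFrame(info_rows)

    if isinstance(cfg.scale_selection, int):
        scale = cfg.scale_selection
    elif cfg.scale_selection == "cohort":
        pooled = {
            k: float(np.exp(np.nanmean(np.log(sigma[f"sigma_scale{k}"]))))
            for k in (1, 2, 3)
        }
        from .avalanche import pick_scale

        scale = pick_scale(pooled)
        log.info("cohort bin scale %d (pooled sigma %s)", scale, pooled)
    else:
        scale = None  # per-recording selection below

    atms: dict[str, dict[str, TransitionMatrix]] = {}
    counts = []
    for sid, session, raster in rasters:
        if scale is None:
            rec_scale, _ = select_scale(raster)
        else:
            rec_scale = scale
        atm, n_av = _atm_at_scale(raster, rec_scale, cfg, roi_names)
        atms.setdefault(sid, {})[session] = atm
        counts.append({"scale": rec_scale, "n_avalanches": n_av,
                       "n_short_excluded": atm.n_short})
    sigma = pd.concat([sigma, pd.DataFrame(counts)], axis=1)
    manifest = pd.DataFrame(rows).set_index("subject_id")
    paired = {sid: (d["test"], d["retest"]) for sid, d in atms.items()}
    return paired, manifest, sigma


def _merged_group(g: str) -> str:
    return "UTLE" if g in ("UTLE-L", "UTLE-R") else g


def analyze_cohort(
    atms: Mapping[str, tuple[TransitionMatrix, TransitionMatrix]],
    manifest: pd.DataFrame,
    cfg: PipelineConfig,
    sigma: pd.DataFrame | None = None,
) -> CohortResults:
    """Group-level fingerprinting, stability and statistics from per-subject
    test/retest ATMs.

    Fingerprint indices are computed within each display group's own
    identifiability matrix (HC, UTLE-L, UTLE-R, BTLE); for the omnibus and
    post-hoc statistics the two unilateral groups are pooled into one UTLE
    group, mirroring how the figures and the tests are organized.
    """
    rng = np.random.default_rng(cfg.seed)
    by_group: dict[str, list[str]] = {}
    for sid in atms:
        by_group.setdefault(str(manifest.loc[sid, "group"]), []).append(sid)

    ims, fp_frames, stab = {}, [], {}
    for g, sids in by_group.items():
        if len(sids) < 2:
            continue
        test = [atms[s][0] for s in sids]
        retest = [atms[s][1] for s in sids]
        im = identifiability_matrix(test, retest, subject_ids=sids, group=g)
        ims[g] = im
        df = fingerprint_scores(im)
        df["group"] = g
        fp_frames.append(df)
        if len(sids) >= 3:
            es = edge_icc(test, retest, group=g)
            stab[g] = {
                "edge": es,
                "node": node_stability(es),
                "mean": group_mean_stability(es),
            }
    fingerprints = pd.concat(fp_frames)
    fingerprints["stat_group"] = [_merged_group(g) for g in fingerprints["group"]]

    # omnibus PERMANOVA per index + FDR over the family of three indices
    labels = fingerprints["stat_group"].to_numpy()
    omnibus_rows = []
    for index_name in ("iself", "iothers", "idiff"):
        res = st.permanova_oneway(
            fingerprints[index_name].to_numpy(),
            labels,
            n_perm=cfg.n_perm,
            seed=int(rng.integers(2**31)),
        )
        omnibus_rows.append(
            {"index": index_name, "F": res.statistic, "p_perm": res.p_perm}
        )
    omnibus = pd.DataFrame(omnibus_rows).set_index("index")
    omnibus["p_fdr"] = st.fdr_bh(omnibus["p_perm"].to_numpy())

    # pairwise post-hocs, FDR within each index's family
    posthoc_rows = []
    pairs = [("HC", "UTLE"), ("HC", "BTLE"), ("UTLE", "BTLE")]
    for index_name in ("iself", "iothers", "idiff"):
        ps = []
        for a, b in pairs:
            va = fingerprints.loc[fingerprints["stat_group"] == a, index_name]
            vb = fingerprints.loc[fingerprints["stat_group"] == b, index_name]
            res = st.perm_posthoc(
                va.to_numpy(), vb.to_numpy(), n_perm=cfg.n_perm,
                seed=int(rng.integers(2**31)),
            )
            ps.append(res.p_perm)
            posthoc_rows.append(
                {
                    "index": index_name,
                    "a": a,
                    "b": b,
                    "mean_a": float(va.mean()),
                    "mean_b": float(vb.mean()),
                    "abs_diff": res.statistic,
                    "p_perm": res.p_perm,
                }
            )
        adj = st.fdr_bh(np.array(ps))
        for off, q in enumerate(adj):
            posthoc_rows[len(posthoc_rows) - len(pairs) + off]["p_fdr"] = float(q)
    posthoc = pd.DataFrame(posthoc_rows)

    # clinical fingerprint: every patient vs the HC reference
    hc_ids = by_group.get("HC", [])
    patients = [s for g, ss in by_group.items() if g != "HC" for s in ss]
    icl = iclinical(
        {s: atms[s] for s in patients}, [atms[s] for s in hc_ids]
    )

    results = CohortResults(
        atms=dict(atms),
        manifest=manifest,
        sigma=sigma if sigma is not None else pd.DataFrame(),
        fingerprints=fingerprints,
        identifiability=ims,
        stability=stab,
        omnibus=omnibus,
        posthoc=posthoc,
        iclinical=icl,
    )

    # correlation of Iclinical with the neuropsychological battery (UTLE),
    # FDR-corrected across the battery
    utle = [s for s in patients if _merged_group(str(manifest.loc[s, "group"])) == "UTLE"]
    score_cols = [
        c
        for c in (
            "rocft_recall", "digit_span", "corsi", "rocft_copy",
            "ravlt_immediate", "ravlt_delayed", "tmt_a", "tmt_b",
        )
        if c in manifest.columns
    ]
    if utle and score_cols:
        rows = []
        for col in score_cols:
            scores = manifest.loc[utle, col].astype(float)
            ok = scores.notna()
            if ok.sum() >= 3:
                r, p = st.pearson_test(icl[utle][ok.to_numpy()], scores[ok])
                rows.append({"score": col, "r": r, "p": p, "n": int(ok.sum())})
        if rows:
            cc = pd.DataFrame(rows).set_index("score")
            cc["p_fdr"] = st.fdr_bh(cc["p"].to_numpy())
            results.clinical_correlations = cc

    # multilinear model: hemisphere, gender, age, Iclinical -> recall (UTLE)
    if utle and "rocft_recall" in manifest.columns:
        sub = manifest.loc[utle]
        ok = sub["rocft_recall"].notna()
        if ok.sum() >= 2 * cfg.k_folds:
            sub = sub.loc[ok]
            X = pd.DataFrame(
                {
                    "hemisphere": (sub["hemisphere"] == "R").astype(float),
                    "gender": (sub["gender"] == "F").astype(float),
                    "age": sub["age"].astype(float),
                    "iclinical": icl[sub.index].to_numpy(),
                },
                index=sub.index,
            )
            results.regression = st.nested_cv_regression(
                X,
                sub["rocft_recall"].astype(float).to_numpy(),
                k=cfg.k_folds,
                n_iter=cfg.n_iter,
                seed=int(rng.integers(2**31)),
            )
    return results


def run_pipeline(
    config: Mapping[str, Any], out_dir: str | Path
) -> CohortResults:
    """Simulate (or load) a cohort, analyze it, and write all outputs.

    ``config`` keys: ``simulate`` (CohortSpec field overrides), pipeline
    fields (``threshold``, ``use_s``, ``delta_bins``, ``n_perm``, ``k_folds``,
    ``n_iter``), and ``seed``.  Outputs: per-session ATM matrices, the sigma
    table, per-group IM / fingerprint / ICC tables, statistics tables, and a
    reproducibility log of every seed and parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(
        **{
            k: config[k]
            for k in (
                "threshold", "use_s", "delta_bins", "scale_selection",
                "n_perm", "k_folds", "n_iter", "seed",
            )
            if k in config
        }
    )
    spec = CohortSpec(**config.get("simulate", {}))
    if "seed" in config and "seed" not in config.get("simulate", {}):
        spec.seed = int(config["seed"])

    try:
        atms, manifest, sigma = process_cohort(spec, cfg)
    except ValueError as exc:
        raise RuntimeError(f"stage 'avalanche/atm' failed: {exc}") from exc
    atm_dir = out / "atm"
    atm_dir.mkdir(exist_ok=True)
    for sid, (atm_t, atm_r) in atms.items():
        write_matrix(atm_dir / f"{sid}_test.tsv", atm_t, {"subject_id": sid})
        write_matrix(atm_dir / f"{sid}_retest.tsv", atm_r, {"subject_id": sid})

    results = analyze_cohort(atms, manifest, cfg, sigma=sigma)

    write_manifest(out / "manifest.tsv", manifest)
    sigma.to_csv(out / "sigma.tsv", sep="\t", index=False)
    results.fingerprints.to_csv(out / "fingerprints.tsv", sep="\t")
    results.omnibus.to_csv(out / "omnibus.tsv", sep="\t")
    results.posthoc.to_csv(out / "posthoc.tsv", sep="\t", index=False)
    results.iclinical.to_frame().to_csv(out / "iclinical.tsv", sep="\t")
    for g, im in results.identifiability.items():
        write_matrix(out / f"im_{g}.tsv", im)
    node_rows = {}
    for g, d in results.stability.items():
        write_matrix(out / f"icc_{g}.tsv", d["edge"])
        node_rows[g] = d["node"]
    if node_rows:
        pd.DataFrame(node_rows).to_csv(out / "node_stability.tsv", sep="\t")
    if results.clinical_correlations is not None:
        results.clinical_correlations.to_csv(out / "clinical_correlation.tsv", sep="\t")
    if results.regression is not None:
        rep = results.regression
        (out / "regression.json").write_text(
            json.dumps(
                {
                    "beta": rep.beta.to_dict(),
                    "beta_p": rep.beta_p.to_dict(),
                    "F": rep.f_stat,
                    "df": list(rep.df),
                    "F_p": rep.f_p,
                    "r2_cv": rep.r2,
                    "nrmse_cv": rep.nrmse,
                    "spearman_cv": rep.spearman,
                    "n_iterations": rep.n_iterations,
                },
                indent=1,
            )
        )
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "pipeline": cfg.__dict__,
                "cohort": {
                    k: v for k, v in spec.__dict__.items() if not k.startswith("_")
                },
                "n_subjects": len(atms),
                "group_means_icc": {
                    g: d["mean"] for g, d in results.stability.items()
                },
            },
            indent=1,
            default=str,
        )
    )
    return results
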