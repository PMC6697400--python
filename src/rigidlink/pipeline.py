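"""End-to-end study flow.

simulate -> score behavior -> validate randomness -> VBM + conjunction ->
ROI statistics -> mediation -> latent-factor model -> replication-style
strata tests, from one config, with per-stage seeds, logging and a
machine-readable JSON report. Identical config + seed gives a
byte-identical report.
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

from . import behavior as bhv
from . import inference, randomwalk, vbm
from .io import read_cohort, spec_to_dict, write_cohort
from .synthetic import CohortDataset, CohortSpec, generate_cohort

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "StageError"]

log = logging.getLogger("rigidlink.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """One config drives the full analysis.

    Either ``spec`` (simulate a cohort) or ``data_dir`` (load a cohort
    written by ``rigidlink.io.write_cohort``) supplies the inputs.
    """

    spec: CohortSpec = field(default_factory=CohortSpec)
    data_dir: str | None = None
    out_dir: str | None = None
    q: float = 0.05
    n_boot: int = 2000
    seed: int = 0
    group_diff_tail: str = "less"  # ASD < TD replication contrast
    include_walk: bool = True
    walk_steps: int = 100_000
    walk_p_trans: tuple = (0.5, 0.6, 0.7, 0.8, 0.9)
    walk_n_hidden: tuple = (1, 2, 3, 4, 5)
    write_artifacts: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = spec_to_dict(self.spec)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    content: dict

    def to_json(self) -> str:
        return json.dumps(self.content, sort_keys=True, indent=2, default=_default)


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(o)}")


def _stage(name: str, seed, fn, report: dict):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:
        log.error("stage=%s seed=%s status=failed error=%s", name, seed, exc)
        raise StageError(name, exc) from exc
    elapsed = time.perf_counter() - t0
    log.info("stage=%s seed=%s elapsed=%.2fs", name, seed, elapsed)
    # elapsed time stays in the log only, so equal config+seed reruns
    # produce byte-identical reports
    report.setdefault("stages", {})[name] = {"seed": seed, "status": "ok"}
    return out


def _pooled_run_lengths(cohort: CohortDataset, subjects: list[str]) -> np.ndarray:
    """Pool spontaneous task repetition lengths across the given subjects."""
    spont = cohort.trials[
        (cohort.trials["mode"] == "spontaneous")
        & (cohort.trials["subject"].isin(subjects))
    ]
    lengths: list[int] = []
    for (_, _), run_df in spont.groupby(["subject", "run"], sort=False):
        labels = bhv.classify_trials(run_df)
        kept = [l for l in labels if l != "unclassifiable"]
        lengths.extend(bhv.repetition_runs(kept))
    return np.asarray(lengths)


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute every stage in dependency order; returns the report and
    (optionally) writes TSV/JSON artifacts to ``config.out_dir``."""
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    seeds = {
        "simulate": int(seeds[0]),
        "walk": int(seeds[1]),
        "mediation": int(seeds[2]),
        "voxel_mediation": int(seeds[3]),
    }
    report: dict = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seeds": seeds,
            "versions": _versions(),
        }
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------ simulate
    def sim():
        if config.data_dir:
            return read_cohort(config.data_dir)
        spec = dataclasses.replace(config.spec, seed=seeds["simulate"])
        cohort = generate_cohort(spec)
        if out_dir and config.write_artifacts:
            write_cohort(cohort, out_dir / "cohort")
        return cohort

    cohort = _stage("simulate", seeds["simulate"], sim, report)

    # ------------------------------------------------------------ behavior
    def score():
        table = bhv.score_cohort(cohort)
        if out_dir and config.write_artifacts:
            table.to_csv(out_dir / "behavior.tsv", sep="\t", index=False)
        return table

    table = _stage("behavior", None, score, report)
    asd = table[table["group"] == "ASD"].reset_index(drop=True)
    td = table[table["group"] == "TD"].reset_index(drop=True)

    def comparisons():
        out = {}
        for col, name in [
            ("median_percept_duration_s", "percept_duration"),
            ("median_repetition_length", "repetition_length"),
            ("switch_cost_ms", "spont_switch_cost"),
            ("instr_switch_cost_ms", "instr_switch_cost"),
            ("instr_accuracy", "instr_accuracy"),
        ]:
            t, dof, p = inference.two_sample_t(asd[col], td[col])
            out[name] = {
                "t": t, "dof": dof, "p": p,
                "cohens_d": inference.cohens_d(asd[col], td[col]),
                "mean_asd": float(asd[col].mean()),
                "mean_td": float(td[col].mean()),
            }
        r = inference.correlate(
            asd["median_percept_duration_s"], asd["median_repetition_length"]
        )
        out["behavior_correlation_asd"] = {
            "method": r.method, "r": r.coefficient, "p": r.p, "n": r.n,
        }
        rrb = asd["ados_rrb"].to_numpy()
        groups = [
            asd["median_repetition_length"].to_numpy()[rrb == lev]
            for lev in np.unique(rrb)
            if np.sum(rrb == lev) > 0
        ]
        if len(groups) >= 2:
            f, dof_f, p = inference.one_way_anova(groups)
            out["repetition_by_rrb_anova"] = {"F": f, "dof": list(dof_f), "p": p}
        out["bonferroni"] = {
            "three_indices": inference.bonferroni_alpha(0.05, 3),
            "two_correlations": inference.bonferroni_alpha(0.05, 2),
        }
        return out

    report["group_comparisons"] = _stage("comparisons", None, comparisons, report)

    # ------------------------------------------------------------ randomness
    if config.include_walk:

        def walk():
            out = {}
            for group, sub in [("TD", td), ("ASD", asd)]:
                lengths = _pooled_run_lengths(cohort, list(sub["subject"]))
                emp = randomwalk.duration_distribution(lengths)
                grid = randomwalk.randomness_grid(
                    emp,
                    p_trans_grid=config.walk_p_trans,
                    n_hidden_grid=config.walk_n_hidden,
                    n_steps=config.walk_steps,
                    seed=seeds["walk"],
                )
                best = grid.p_trans_grid[int(np.argmin(grid.mean_kl_by_p_trans))]
                out[group] = {
                    "p_trans_grid": grid.p_trans_grid.tolist(),
                    "n_hidden_grid": grid.n_hidden_grid.tolist(),
                    "kl": np.round(grid.kl, 6).tolist(),
                    "mean_kl_by_p_trans": np.round(grid.mean_kl_by_p_trans, 6).tolist(),
                    "best_p_trans": float(best),
                }
                if out_dir and config.write_artifacts:
                    pd.DataFrame(
                        grid.kl,
                        index=[f"p={p:.1f}" for p in grid.p_trans_grid],
                        columns=[f"h={h}" for h in grid.n_hidden_grid],
                    ).to_csv(out_dir / f"kl_grid_{group.lower()}.tsv", sep="\t")
            return out

        report["randomness"] = _stage("randomness", seeds["walk"], walk, report)
    else:
        report["randomness"] = "skipped"

    # ------------------------------------------------------------ neuro
    if cohort.images is None:
        for key in ("vbm", "roi", "mediation", "sem", "replication"):
            report[key] = "skipped"
        report["status"] = "ok"
        return _finalize(report, out_dir, config)

    images = cohort.images
    asd_idx = cohort.group_index("ASD")
    td_idx = cohort.group_index("TD")
    order = {s: i for i, s in enumerate(cohort.subjects["subject"])}
    asd_rows = np.array([order[s] for s in asd["subject"]])
    td_rows = np.array([order[s] for s in td["subject"]])
    covs = asd[["age", "full_iq"]].to_numpy(dtype=float)

    def run_vbm():
        out = {}
        neg_masks = {}
        for col, name in [
            ("median_percept_duration_s", "percept_duration"),
            ("median_repetition_length", "repetition_length"),
        ]:
            smap = vbm.voxelwise_regression(
                type(images)(
                    values=images.values[asd_rows],
                    mask=images.mask,
                    voxel_size_mm=images.voxel_size_mm,
                    planted=images.planted,
                ),
                asd[col].to_numpy(dtype=float),
                covariates=covs,
                regressor_name=name,
            )
            surv = vbm.fdr_threshold(smap, config.q)
            pos, neg = vbm.signed_maps(smap, surv)
            neg_masks[name] = neg
            clusters = vbm.extract_clusters(
                neg, smap.t_values, voxel_size_mm=images.voxel_size_mm
            )
            out[name] = {
                "n_fdr_voxels": int(surv.sum()),
                "n_positive": int(pos.sum()),
                "n_negative": int(neg.sum()),
                "dof": smap.dof,
                "negative_clusters": clusters.table.to_dict(orient="records"),
            }
            if out_dir and config.write_artifacts:
                clusters.table.to_csv(
                    out_dir / f"clusters_{name}.tsv", sep="\t", index=False
                )
        conj = vbm.conjunction(
            neg_masks["percept_duration"], neg_masks["repetition_length"]
        )
        out["conjunction"] = {"n_voxels": int(conj.sum())}
        planted = images.planted
        if planted.any():
            overlap = int((conj & planted).sum())
            out["conjunction"]["planted_voxels"] = int(planted.sum())
            out["conjunction"]["planted_overlap"] = overlap
            out["conjunction"]["planted_recovery"] = overlap / int(planted.sum())
        return out, conj

    (vbm_out, conj_mask) = _stage("vbm", None, run_vbm, report)
    report["vbm"] = vbm_out

    def roi_stats():
        out = {}
        roi = conj_mask if conj_mask.any() else None
        out["roi_source"] = "conjunction" if roi is not None else "empty"
        wb = np.array(
            [vbm.whole_brain_gmv(v, images.mask) for v in images.values]
        )
        t, dof, p = inference.two_sample_t(wb[asd_idx], wb[td_idx])
        out["whole_brain_gmv_asd_vs_td"] = {"t": t, "dof": dof, "p": p}
        for roi_mask, tag in [(roi, "conjunction"), (images.planted, "planted")]:
            if roi_mask is None or not roi_mask.any():
                continue
            roi_mean = np.array(
                [vbm.roi_mean_gmv(v, roi_mask) for v in images.values]
            )
            rel = np.array(
                [
                    vbm.relative_gmv(v, roi_mask, images.mask)
                    for v in images.values
                ]
            )
            block = {}
            for col, name in [
                ("median_percept_duration_s", "percept_duration"),
                ("median_repetition_length", "repetition_length"),
            ]:
                r = inference.correlate(roi_mean[asd_rows], asd[col])
                block[f"corr_{name}"] = {"r": r.coefficient, "p": r.p}
                rr = inference.correlate(rel[asd_rows], asd[col])
                block[f"relative_corr_{name}"] = {"r": rr.coefficient, "p": rr.p}
            t, dof, p = inference.two_sample_t(roi_mean[asd_idx], roi_mean[td_idx])
            block["group_t"] = {"t": t, "dof": dof, "p": p}
            rrb = asd["ados_rrb"].to_numpy(dtype=float)
            try:
                t_s, p_s = inference.rrb_strata_test(roi_mean[asd_rows], rrb)
                block["rrb_strata"] = {"t": t_s, "p": p_s}
            except ValueError as exc:
                block["rrb_strata"] = {"error": str(exc)}
            out[tag] = block
        return out

    report["roi"] = _stage("roi", None, roi_stats, report)

    def run_mediation():
        out = {}
        x = asd["median_percept_duration_s"].to_numpy(dtype=float)
        y = asd["median_repetition_length"].to_numpy(dtype=float)
        for tag, roi_mask in [
            ("conjunction", conj_mask if conj_mask.any() else None),
            ("planted", images.planted if images.planted.any() else None),
        ]:
            if roi_mask is None:
                out[tag] = "empty-roi"
                continue
            m = np.array(
                [vbm.roi_mean_gmv(images.values[i], roi_mask) for i in asd_rows]
            )
            res = inference.mediate(
                x, m, y, n_boot=config.n_boot, seed=seeds["mediation"],
                standardize=True,
            )
            pc = inference.partial_correlation(x, y, m)
            out[tag] = {
                "alpha": res.alpha, "beta": res.beta, "gamma": res.gamma,
                "indirect": res.indirect, "ci": [res.ci_lower, res.ci_upper],
                "p_indirect": res.p_indirect, "n_boot": res.n_boot,
                "partial_correlation_given_roi": pc,
            }
        return out

    report["mediation"] = _stage("mediation", seeds["mediation"], run_mediation, report)

    def run_sem():
        roi_mask = conj_mask if conj_mask.any() else images.planted
        if not roi_mask.any():
            return "empty-roi"
        m = np.array(
            [vbm.roi_mean_gmv(images.values[i], roi_mask) for i in asd_rows]
        )
        X = np.column_stack(
            [
                asd["median_percept_duration_s"].to_numpy(dtype=float),
                asd["median_repetition_length"].to_numpy(dtype=float),
                -m,  # flexibility loads opposite to GMV deficit sign convention
            ]
        )
        fit = inference.fit_latent_model(X, standardize=True)
        return {
            "loadings": np.round(fit.loadings, 4).tolist(),
            "residual_variances": np.round(fit.residual_variances, 4).tolist(),
            "agfi": fit.agfi, "cfi": fit.cfi, "rmsea": fit.rmsea,
            "srmr": fit.srmr, "chi2": fit.chi2, "df": fit.df,
            "converged": fit.converged, "heywood": fit.heywood,
        }

    report["sem"] = _stage("sem", None, run_sem, report)

    def replication():
        from types import SimpleNamespace

        smap, fdr_mask = vbm.group_difference_map(
            SimpleNamespace(
                values=images.values[asd_idx], mask=images.mask,
                voxel_size_mm=images.voxel_size_mm,
            ),
            SimpleNamespace(
                values=images.values[td_idx], mask=images.mask,
                voxel_size_mm=images.voxel_size_mm,
            ),
            q=config.q,
            tail=config.group_diff_tail,
        )
        clusters = vbm.extract_clusters(
            fdr_mask, smap.t_values, voxel_size_mm=images.voxel_size_mm
        )
        rrb = asd["ados_rrb"].to_numpy(dtype=float)
        rows = []
        for rec in clusters.table.to_dict(orient="records"):
            sel = clusters.labels == rec["label"]
            roi_mean = np.array(
                [vbm.roi_mean_gmv(images.values[i], sel) for i in asd_rows]
            )
            try:
                t_s, p_s = inference.rrb_strata_test(roi_mean, rrb)
                rec.update({"rrb_t": t_s, "rrb_p": p_s})
            except ValueError as exc:
                rec.update({"rrb_error": str(exc)})
            rows.append(rec)
        planted = images.planted
        overlap = (
            int((fdr_mask & planted).sum()) / int(planted.sum())
            if planted.any()
            else None
        )
        return {
            "n_fdr_voxels": int(fdr_mask.sum()),
            "tail": config.group_diff_tail,
            "planted_recovery": overlap,
            "clusters": rows,
        }

    report["replication"] = _stage("replication", None, replication, report)
    report["status"] = "ok"
    return _finalize(report, out_dir, config)


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "rigidlink": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def _finalize(report: dict, out_dir: Path | None, config: AnalysisConfig) -> AnalysisReport:
    rep = AnalysisReport(content=report)
    if out_dir and config.write_artifacts:
        (out_dir / "report.json").write_text(rep.to_json())
    return rep
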