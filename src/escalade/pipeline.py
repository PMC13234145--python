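"""End-to-end orchestration over synthetic or user-supplied data.

A single config drives every stage in dependency order:

    simulate -> behavior -> lgcm -> gbtm -> de -> wgcna -> prioritize -> validate

Each stage writes plain-text artifacts (TSV/JSON) into the run
directory plus a timestamped provenance log recording seeds, package
versions and thresholds.  All randomness derives from one root seed
through named per-stage substreams, so a rerun with the same config is
numerically identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import escalade
from escalade import behavior as bhv
from escalade import de as de_mod
from escalade import gbtm as gbtm_mod
from escalade import growth as growth_mod
from escalade import prioritize as pri_mod
from escalade import synthetic as syn
from escalade import wgcna as wgcna_mod

STAGES = ["simulate", "behavior", "lgcm", "gbtm", "de", "wgcna", "prioritize", "validate"]
_DEPS = {
    "behavior": ["simulate"],
    "lgcm": ["simulate", "behavior"],
    "gbtm": ["simulate"],
    "de": ["simulate", "gbtm"],
    "wgcna": ["de"],
    "prioritize": ["de", "wgcna"],
    "validate": ["simulate", "gbtm", "prioritize", "behavior"],
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible run.

    ``sim`` holds SimConfig overrides for the synthetic generator;
    ``stages`` toggles stages (dependencies are validated);
    thresholds mirror the analysis defaults: count filter ``min_total``,
    permutation count ``n_perms``, network ``beta`` / ``min_size`` /
    ``merge_thresh``, stepwise ``f_enter`` / ``f_remove``, ``fdr``.
    """

    seed: int = 0
    sim: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    g_range: tuple = (1, 2, 3, 4)
    min_total: int = 10
    n_perms: int = 200
    beta: int = 17
    min_size: int = 30
    merge_thresh: float = 0.2
    cut_quantile: float = 0.99
    wgcna_top_genes: int = 800
    f_enter: float = 2.0
    f_remove: float = 1.0
    fdr: float = 0.05
    window: int = 7
    n_per_group: int = 8
    reference_group: int = 1

    def __post_init__(self):
        for s in self.stages:
            if s not in STAGES:
                raise PipelineError(f"unknown stage {s!r}")
        enabled = {s for s in STAGES if self.stages.get(s, True)}
        for s in enabled:
            for dep in _DEPS.get(s, []):
                if dep not in enabled:
                    raise PipelineError(f"stage {s!r} requires {dep!r} to be enabled")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["g_range"] = list(self.g_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "g_range" in d:
            d["g_range"] = tuple(d["g_range"])
        return cls(**d)


def _stage_seed(root: int, stage: str) -> int:
    """Named deterministic substream seed below 2^31."""
    ss = np.random.SeedSequence([root, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages and write artifacts under ``outdir``.

    Returns a summary report (also written as ``report.json``): chosen
    group count and group sizes, growth-model tests, DE counts at the
    configured FDR, the module-trait table, top priority genes and the
    stepwise validation fit.  Raises :class:`PipelineError` naming the
    failing stage; artifacts from completed stages remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    report: dict = {"stages_run": []}
    enabled = {s for s in STAGES if config.stages.get(s, True)}

    def log(msg: str) -> None:
        with open(log_path, "a") as fh:
            fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}\n")

    log(f"escalade {escalade.__version__} | numpy {np.__version__} | pandas {pd.__version__}")
    log(f"root seed {config.seed}; thresholds: " + json.dumps(
        {k: getattr(config, k) for k in
         ("min_total", "n_perms", "beta", "min_size", "merge_thresh", "f_enter", "f_remove", "fdr")}))
    config.to_yaml(outdir / "config.yaml")

    state: dict = {}

    def run_stage(name, fn):
        if name not in enabled:
            return
        log(f"stage {name}: start")
        try:
            fn()
        except Exception as exc:
            log(f"stage {name}: FAILED ({exc})")
            raise PipelineError(
                f"stage {name!r} failed: {exc}; completed artifacts in {outdir}"
            ) from exc
        report["stages_run"].append(name)
        log(f"stage {name}: done")

    # ------------------------------------------------------------------ simulate
    def stage_simulate():
        sim_kwargs = dict(config.sim)
        sim_kwargs["seed"] = _stage_seed(config.seed, "simulate")
        cfg = syn.SimConfig(**sim_kwargs)
        state["sim_cfg"] = cfg
        panel, truth = syn.simulate_behavior(cfg)
        state["panel"], state["truth"] = panel, truth
        _write_tsv(panel, outdir / "behavior_panel.tsv", index=False)
        rng = np.random.default_rng(_stage_seed(config.seed, "simulate") + 7)
        # sucrose PR breakpoints: cohort-level mean/sd chosen to mimic a
        # stabilized final-window distribution; per-rat level tied to the
        # latent covariate draw so the growth stage has signal to find
        rats = truth.covariate.index
        rows = []
        for rat in rats:
            base = 47.5 + 29.8 * truth.covariate.loc[rat]
            for day in range(1, 8):
                rows.append((rat, day, max(base + rng.normal(0, 5.0), 0.0)))
        bp = pd.DataFrame(rows, columns=["rat_id", "day", "breakpoint"])
        state["breakpoints"] = bp
        _write_tsv(bp, outdir / "breakpoints.tsv", index=False)
        truth_json = {
            "group_labels": {str(k): int(v) for k, v in truth.group_labels.items()},
            "covariate": {str(k): float(v) for k, v in truth.covariate.items()},
        }
        (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))

    # ------------------------------------------------------------------ behavior
    def stage_behavior():
        summ = bhv.breakpoint_zscores(state["breakpoints"], window=3)
        state["sucrose"] = summ
        out = pd.DataFrame({"breakpoint_mean": summ.means, "z_sucrose": summ.z})
        _write_tsv(out, outdir / "sucrose_summary.tsv")
        report["sucrose"] = {"overall_mean": summ.overall_mean, "overall_sd": summ.overall_sd}

    # ------------------------------------------------------------------ lgcm
    def stage_lgcm():
        fit = growth_mod.fit_lgcm(
            state["panel"], state["sucrose"].z, order=2,
            seed=_stage_seed(config.seed, "lgcm"),
        )
        state["lgcm"] = fit
        tests = {}
        for which in ("overall", "initial", "change"):
            stat, df, p = growth_mod.test_covariate(fit, which)
            tests[which] = {"stat": stat, "df": df, "p": p}
        days = np.arange(1, state["sim_cfg"].n_days + 1)
        curves = pd.DataFrame(
            {f"z={z:+d}": growth_mod.predict_trajectory(fit, z, days) for z in (-1, 0, 1)},
            index=pd.Index(days, name="day"),
        )
        _write_tsv(curves, outdir / "lgcm_curves.tsv")
        fit_json = {
            "beta": fit.beta.tolist(),
            "G": fit.G.tolist(),
            "sigma2": fit.sigma2,
            "loglik": fit.loglik,
            "n_rats": fit.n_rats,
            "n_obs": fit.n_obs,
            "tests": tests,
        }
        (outdir / "lgcm_fit.json").write_text(json.dumps(fit_json, indent=1))
        report["lgcm_tests"] = {k: v["p"] for k, v in tests.items()}

    # ------------------------------------------------------------------ gbtm
    def stage_gbtm():
        spec = gbtm_mod.TrajModelSpec.escalation(seed=_stage_seed(config.seed, "gbtm"))
        table, chosen, fits = gbtm_mod.select_groups(state["panel"], spec, config.g_range)
        fit = fits[chosen]
        state["gbtm"] = fit
        _write_tsv(table, outdir / "gbtm_selection.tsv")
        assign = pd.DataFrame(
            {"group": fit.assignment, "max_posterior": fit.posterior.max(axis=1)}
        )
        _write_tsv(assign, outdir / "gbtm_assignments.tsv")
        (outdir / "gbtm_fit.json").write_text(json.dumps(
            {
                "n_groups": int(fit.n_groups),
                "pi": fit.pi.tolist(),
                "sigma": np.asarray(fit.sigma).tolist(),
                "coefs": {syn.OUTCOMES[k]: fit.coefs[k].tolist() for k in range(3)},
                "loglik": fit.loglik,
                "bic": fit.bic,
            }, indent=1))
        report["gbtm"] = {
            "chosen_g": int(chosen),
            "group_sizes": fit.assignment.value_counts().sort_index().to_dict(),
        }

    # ------------------------------------------------------------------ de
    def stage_de():
        fit = state["gbtm"]
        truth = state["truth"]
        # biological replicates: up to n_per_group rats per fitted group
        rng = np.random.default_rng(_stage_seed(config.seed, "de"))
        chosen_rats = []
        for g in sorted(fit.assignment.unique()):
            members = list(fit.assignment.index[fit.assignment == g])
            rng.shuffle(members)
            chosen_rats.extend(members[: config.n_per_group])
        groups = fit.assignment.loc[chosen_rats]
        sim_cfg = state["sim_cfg"]
        counts, meta, ctruth = syn.simulate_counts(sim_cfg, truth.group_labels.loc[chosen_rats])
        meta["group"] = groups.values  # analysis runs on fitted groups
        state["counts_truth"] = ctruth
        cm = de_mod.CountMatrix(counts=counts, meta=meta)
        cm = de_mod.filter_low_counts(cm, min_total=config.min_total)
        cm.size_factors = de_mod.size_factors_median_ratios(cm)
        state["cm"] = cm
        top = str(int(groups.max()))
        ref = str(config.reference_group)
        state["de_contrast"] = ("group", top, ref)
        de = de_mod.fit_nb_wald(cm, contrast=state["de_contrast"])
        p_perm = de_mod.permutation_pvalues(
            cm, statistic="wald", contrast=state["de_contrast"],
            B=max(config.n_perms, 100), seed=_stage_seed(config.seed, "de") + 1,
        )
        de.table["p_perm"] = p_perm
        de.table["q_perm"] = de_mod.bh_adjust(p_perm).values
        de.n_perm_used = max(config.n_perms, 100)
        state["de"] = de
        _write_tsv(de.table, outdir / "de_table.tsv")
        sig = de.table[(de.table["q"] < config.fdr) & (de.table["log2fc"].abs() > 0.5)]
        report["de"] = {
            "contrast": list(state["de_contrast"]),
            "n_genes_tested": int(len(de.table)),
            "n_sig_fdr": int((de.table["q"] < config.fdr).sum()),
            "n_sig_fdr_lfc": int(len(sig)),
            "n_perm_sig_unadj": int((de.table["p_perm"] < 0.05).sum()),
            "min_q_perm": float(de.table["q_perm"].min()),
        }

    # ------------------------------------------------------------------ wgcna
    def stage_wgcna():
        cm = state["cm"]
        norm = np.log1p(cm.normalized())
        var = norm.var(axis=1).sort_values(ascending=False)
        keep = var.index[: config.wgcna_top_genes]
        keep = [g for g in keep if norm.loc[g].std() > 0]
        expr = norm.loc[keep]
        adj = wgcna_mod.signed_adjacency(expr, beta=config.beta)
        tom = wgcna_mod.tom_similarity(adj)
        mods = wgcna_mod.detect_modules(
            tom, expr, min_size=config.min_size, merge_thresh=config.merge_thresh,
            cut_quantile=config.cut_quantile, beta=config.beta,
        )
        mods.kwithin = wgcna_mod.intramodular_connectivity(adj, mods.assignment)
        traits = pd.get_dummies(cm.meta["group"].astype(str)).astype(float)
        traits.columns = [f"group_{c}" for c in traits.columns]
        if "sex" in cm.meta.columns and cm.meta["sex"].nunique() > 1:
            traits["sex"] = (cm.meta["sex"] == sorted(cm.meta["sex"].unique())[1]).astype(float)
        if mods.eigengenes is not None:
            mods.module_trait = wgcna_mod.module_trait_correlation(mods.eigengenes, traits)
            _write_tsv(mods.module_trait, outdir / "module_trait.tsv", index=False)
            _write_tsv(mods.eigengenes, outdir / "eigengenes.tsv")
        _write_tsv(mods.assignment.to_frame(), outdir / "module_assignment.tsv")
        _write_tsv(mods.kwithin.to_frame(), outdir / "kwithin.tsv")
        state["modules"] = mods
        sizes = mods.assignment[mods.assignment != wgcna_mod.GREY].value_counts()
        report["wgcna"] = {"module_sizes": sizes.to_dict()}

    # ------------------------------------------------------------------ prioritize
    def stage_prioritize():
        mods = state["modules"]
        if mods.module_trait is None or not mods.modules:
            raise PipelineError("no modules detected; cannot prioritize")
        # the validation module is the one most positively correlated with
        # membership in the top escalation group
        top_col = f"group_{state['de_contrast'][1]}"
        mt = mods.module_trait
        sub = mt[mt["trait"] == top_col].dropna(subset=["r"])
        best_module = sub.loc[sub["r"].idxmax(), "module"]
        pt = pri_mod.rank_module_genes(state["de"], mods, best_module)
        state["priority"] = pt
        _write_tsv(pt.table, outdir / "priority.tsv")
        report["priority"] = {
            "module": best_module,
            "top_genes": pt.table.index[:10].tolist(),
        }

    # ------------------------------------------------------------------ validate
    def stage_validate():
        fit = state["gbtm"]
        truth = state["truth"]
        cm = state["cm"]
        pt = state["priority"]
        top_genes = pt.table.index[:9].tolist()
        reps = list(cm.meta.index)
        ctruth = state["counts_truth"]
        planted_fc = None
        if ctruth.qpcr_true_fc is not None:
            have = [g for g in top_genes if g in ctruth.qpcr_true_fc.index]
            planted_fc = ctruth.qpcr_true_fc.loc[have] if have else None
            top_genes = have or top_genes
        qpcr, qtruth = syn.simulate_qpcr(
            state["sim_cfg"], truth.group_labels.loc[reps], genes=top_genes,
            true_fc=planted_fc,
        )
        # qPCR tables are keyed by fitted escalation group downstream
        qpcr["group"] = fit.assignment.loc[qpcr["rat_id"]].values
        fc = pri_mod.ddct_fold_change(qpcr, reference_group=config.reference_group)
        _write_tsv(fc, outdir / "qpcr_fold_change.tsv", index=False)
        summ = bhv.combined_zscore(
            state["panel"], fit.assignment,
            reference_group=config.reference_group, window=config.window,
        )
        pc1 = bhv.behavior_pc1(state["panel"], window=config.window)
        out = pd.DataFrame({"z_total": summ.z_total, "pc1": pc1})
        _write_tsv(out, outdir / "behavior_summary.tsv")
        Xfc = fc.pivot_table(index="rat_id", columns="gene", values="fold_change")
        common = Xfc.index.intersection(summ.z_total.index)
        sw = pri_mod.stepwise_regression(
            np.log2(Xfc.loc[common]), summ.z_total.loc[common],
            f_enter=config.f_enter, f_remove=config.f_remove,
        )
        (outdir / "stepwise.json").write_text(json.dumps(
            {
                "selected": sw.selected,
                "coef": sw.coef.to_dict(),
                "r2": sw.r2,
                "f_stat": None if np.isnan(sw.f_stat) else sw.f_stat,
                "p": None if np.isnan(sw.p) else sw.p,
                "pairs": sw.predicted.round(6).to_dict(orient="index"),
            }, indent=1))
        report["validate"] = {"selected": sw.selected, "r2": sw.r2}

    run_stage("simulate", stage_simulate)
    run_stage("behavior", stage_behavior)
    run_stage("lgcm", stage_lgcm)
    run_stage("gbtm", stage_gbtm)
    run_stage("de", stage_de)
    run_stage("wgcna", stage_wgcna)
    run_stage("prioritize", stage_prioritize)
    run_stage("validate", stage_validate)

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    log("pipeline complete")
    return report
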