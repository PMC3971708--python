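"""End-to-end orchestration: fit -> ancestors -> thermometer -> partition.

:func:`run_full_study` chains the whole inference: fit the branch-wise
non-homogeneous model on the (masked) alignment, reconstruct and sample
ancestral sequences, build the tip-GC thermometer, map ancestral
compositions to OGTs, partition sites into slow/fast halves by posterior
mean rate, re-run the fit + reconstruction + thermometry on each
partition, and compare the root's OGT sample set against each root-child
lineage with Wilcoxon rank-sum tests.  The result mirrors the
node x {all, slow, fast} ancestral-temperature table of the study design.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestral import (
    AncestralPosterior,
    composition,
    node_posteriors,
    sample_sequences,
)
from .core_io import (
    Alignment,
    RootedTree,
    SiteMask,
    apply_mask,
    check_pairing,
)
from .inference import (
    FitOptions,
    LikelihoodResult,
    fit_gg,
    partition_sites,
    site_rates,
)
from .substitution_model import GGParams
from .thermometry import (
    OGTEstimate,
    Thermometer,
    build_thermometer,
    compare_nodes,
    estimate_ancestral_ogt,
)

_LOG = logging.getLogger(__name__)

__all__ = ["FullStudyResult", "run_full_study", "params_to_dict", "params_from_dict"]


def package_version() -> str:
    try:
        return _pkg_version("thermotrace")
    except PackageNotFoundError:
        return "unknown"


def params_to_dict(result: LikelihoodResult, model: str, seed: int | None = None
                   ) -> dict:
    """JSON-serializable record of a fitted model."""
    p = result.params
    return {
        "model": model,
        "loglik": result.loglik,
        "aic": result.aic,
        "n_free_params": result.n_free_params,
        "converged": result.converged,
        "n_iterations": result.n_iterations,
        "theta_root": p.theta_root,
        "theta_branch": {str(k): v for k, v in sorted(p.theta_branch.items())},
        "kappa": p.kappa,
        "alpha": p.alpha,
        "n_categories": p.n_categories,
        "seed": seed,
        "package_version": package_version(),
    }


def params_from_dict(d: dict) -> GGParams:
    return GGParams(
        theta_root=float(d["theta_root"]),
        theta_branch={int(k): float(v) for k, v in d["theta_branch"].items()},
        kappa=float(d["kappa"]),
        alpha=float(d["alpha"]),
        n_categories=int(d["n_categories"]),
    )


@dataclass
class _SiteSetResult:
    """Fit + reconstruction + thermometry for one site subset.

    ``ogt`` carries the reported estimates (intervals optionally convolved
    with thermometer calibration error); ``ogt_raw`` maps the composition
    samples through the regression with no added noise and is what node
    comparisons use — the rank-sum test asks whether reconstructed
    *compositions* differ, and iid calibration noise would only mask that.
    """

    fit: LikelihoodResult
    posterior: AncestralPosterior
    thermometer: Thermometer
    ogt: OGTEstimate
    ogt_raw: OGTEstimate
    n_sites: int


@dataclass
class FullStudyResult:
    """Everything :func:`run_full_study` computes, plus a JSON-ready report."""

    site_sets: dict[str, _SiteSetResult]      # 'all', 'slow', 'fast'
    report: dict

    def report_table(self) -> pd.DataFrame:
        rows = []
        for site_set, entry in self.report["estimates"].items():
            for node, est in entry.items():
                rows.append((node, site_set, est["ogt_mean"],
                             est["ogt_lo95"], est["ogt_hi95"]))
        return pd.DataFrame(
            rows, columns=["node", "site_set", "ogt_mean", "ogt_lo95", "ogt_hi95"]
        )


def _focus_nodes(tree: RootedTree) -> dict[str, int]:
    root = tree.root
    c1, c2 = tree.children[root]
    name = lambda v, default: tree.labels[v] or default
    return {
        name(root, "root"): root,
        name(c1, f"node{c1}"): c1,
        name(c2, f"node{c2}"): c2,
    }


def _analyse_site_set(aln: Alignment, tree: RootedTree, ogt: pd.Series,
                      n_samples: int, seed: int, fit_options: FitOptions,
                      n_categories: int, convolve_residual: bool,
                      init, thermometer: Thermometer | None = None
                      ) -> _SiteSetResult:
    fit = fit_gg(aln, tree, init=init, options=fit_options,
                 n_categories=n_categories)
    post = node_posteriors(aln, tree, fit.params)
    samples = sample_sequences(post, n=n_samples, seed=seed)
    comp = composition(samples)
    if thermometer is None:
        thermometer = build_thermometer(aln.gc_content(), ogt)
    est = estimate_ancestral_ogt(comp, thermometer,
                                 convolve_residual=convolve_residual,
                                 seed=seed + 1)
    est_raw = estimate_ancestral_ogt(comp, thermometer,
                                     convolve_residual=False)
    return _SiteSetResult(fit, post, thermometer, est, est_raw, aln.sites)


def run_full_study(aln: Alignment, tree: RootedTree, ogt: pd.Series,
                   mask: SiteMask | None = None, *,
                   n_categories: int = 8, n_samples: int = 100,
                   rate_quantile: float = 0.5, seed: int = 0,
                   fit_options: FitOptions | None = None,
                   convolve_residual: bool = True,
                   partition_thermometer: str = "all_sites"
                   ) -> FullStudyResult:
    """Run the complete ancestral-OGT analysis on one dataset.

    Per-partition analyses refit every substitution-model parameter on the
    sub-alignment.  By default (``partition_thermometer='all_sites'``) the
    slow- and fast-site ancestral compositions are mapped through the
    thermometer calibrated on the complete (masked) dataset, keeping a
    single temperature scale across site sets; ``'refit'`` instead
    recalibrates the regression on each partition's own tip compositions.
    """
    if partition_thermometer not in ("all_sites", "refit"):
        raise ValueError("partition_thermometer must be 'all_sites' or 'refit'")
    check_pairing(aln, tree, ogt)
    opts = fit_options or FitOptions(n_starts=1)
    masked = apply_mask(aln, mask) if mask is not None else aln

    results: dict[str, _SiteSetResult] = {}
    results["all"] = _analyse_site_set(
        masked, tree, ogt, n_samples, seed, opts, n_categories,
        convolve_residual, init="auto",
    )
    shared_th = (results["all"].thermometer
                 if partition_thermometer == "all_sites" else None)
    profile = site_rates(masked, tree, results["all"].fit.params)
    part = partition_sites(profile, rate_quantile)
    for name, sub_mask in (("slow", part.slow), ("fast", part.fast)):
        sub = apply_mask(masked, sub_mask)
        results[name] = _analyse_site_set(
            sub, tree, ogt, n_samples, seed + {"slow": 100, "fast": 200}[name],
            opts, n_categories, convolve_residual, init="auto",
            thermometer=shared_th,
        )

    focus = _focus_nodes(tree)
    root_name = next(iter(focus))
    estimates: dict[str, dict] = {}
    comparisons: dict[str, dict] = {}
    for name, res in results.items():
        estimates[name] = {}
        for label, v in focus.items():
            estimates[name][label] = {
                "ogt_mean": res.ogt.mean[v],
                "ogt_lo95": res.ogt.lower[v],
                "ogt_hi95": res.ogt.upper[v],
            }
        comparisons[name] = {}
        root_v = focus[root_name]
        for label, v in focus.items():
            if v == root_v:
                continue
            stat, p, direction = compare_nodes(
                res.ogt_raw.samples[root_v], res.ogt_raw.samples[v]
            )
            comparisons[name][f"{root_name}_vs_{label}"] = {
                "statistic": stat, "p_value": p, "direction": direction,
                "root_cooler": bool(
                    direction == "b_hotter"
                ),
            }
    report = {
        "package_version": package_version(),
        "seed": seed,
        "n_samples": n_samples,
        "n_categories": n_categories,
        "rate_quantile": rate_quantile,
        "rate_threshold": part.threshold,
        "n_sites": {name: res.n_sites for name, res in results.items()},
        "fits": {name: params_to_dict(res.fit, "gg", seed)
                 for name, res in results.items()},
        "thermometers": {
            name: {
                "slope": res.thermometer.slope,
                "intercept": res.thermometer.intercept,
                "residual_sd": res.thermometer.residual_sd,
                "n": res.thermometer.n,
                "spearman_rho": res.thermometer.spearman_rho,
                "spearman_p": res.thermometer.spearman_p,
            } for name, res in results.items()
        },
        "estimates": estimates,
        "comparisons": comparisons,
    }
    return FullStudyResult(results, report)


def write_report(result: FullStudyResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True) + "\n"
    )
    result.report_table().to_csv(out / "report.tsv", sep="\t", index=False)
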