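"""End-to-end orchestration with provenance.

Runs simulate → compose → network → stepwise logratio selection →
penalized log-contrast regression → logratio OLS, writes every stage's
output plus a markdown report into a run directory, and serializes the
exact configuration and seed so any artifact can be reproduced.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tree import (
    default_tree,
    derive_other,
    read_panel_csv,
    replace_zeros,
    to_composition,
    validate_subjects,
)
from .logratios import all_pairwise_logratios, srda_select, total_logratio_variance, pairwise_correlations
from .network import infer_network
from .logcontrast import fit_with_inference
from .outcomes import compare_r2, fit_logratio_ols
from .simulate import default_ground_truth, generate_cohort

log = logging.getLogger("lymphocoda")

_DEFAULTS = dict(
    seed=0,
    n_subjects=2000,
    outcomes=["cdi", "srh", "frailty_level"],
    tiers=[1, 2, 3],
    srda_target_fraction=0.90,
    network_methods=["glasso", "mb"],
    stars_subsamples=50,
    stars_threshold=0.05,
    bootstrap_reps=200,
    renormalize_after_zero_replacement=False,
    panel_csv=None,
    covariates_csv=None,
    outcomes_csv=None,
)


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys are rejected on load."""

    seed: int = 0
    n_subjects: int = 2000
    outcomes: list = field(default_factory=lambda: ["cdi", "srh", "frailty_level"])
    tiers: list = field(default_factory=lambda: [1, 2, 3])
    srda_target_fraction: float = 0.90
    network_methods: list = field(default_factory=lambda: ["glasso", "mb"])
    stars_subsamples: int = 50
    stars_threshold: float = 0.05
    bootstrap_reps: int = 200
    renormalize_after_zero_replacement: bool = False
    panel_csv: str | None = None
    covariates_csv: str | None = None
    outcomes_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every stage and write outputs + report under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())
    (outdir / "provenance.json").write_text(
        json.dumps(
            {
                "lymphocoda": __version__,
                "python": platform.python_version(),
                "seed": config.seed,
            },
            indent=2,
        )
    )
    tree = default_tree()
    (outdir / "tree.json").write_text(tree.to_json())

    # ---- stage: input (simulate or load) --------------------------------
    if config.panel_csv:
        panel = read_panel_csv(config.panel_csv, tree)
        covariates = (
            pd.read_csv(config.covariates_csv, index_col="subject_id")
            if config.covariates_csv
            else None
        )
        outcomes = (
            pd.read_csv(config.outcomes_csv, index_col="subject_id")
            if config.outcomes_csv
            else None
        )
    else:
        cohort = generate_cohort(config.n_subjects, default_ground_truth(), seed=config.seed)
        cohort.write(outdir / "simulated")
        panel, covariates, outcomes = cohort.panel, cohort.covariates, cohort.outcomes
    log.info("input: %d subjects", len(panel))

    # ---- stage: compose --------------------------------------------------
    kept, exclusions = validate_subjects(panel, tree)
    exclusions.to_json(outdir / "exclusions.json", orient="records", indent=2)
    log.info("validate: kept %d, excluded %d", len(kept), len(exclusions))
    comp = to_composition(derive_other(kept, tree), tree)
    comp_z = replace_zeros(comp, renormalize=config.renormalize_after_zero_replacement)
    comp_z.proportions.rename_axis("subject_id").to_csv(outdir / "composition.csv")
    n_zero = int(comp_z.zero_replaced.to_numpy().sum()) if comp_z.zero_replaced is not None else 0
    log.info("compose: %d zero cells replaced", n_zero)
    if covariates is not None:
        covariates = covariates.loc[kept.index]
    if outcomes is not None:
        outcomes = outcomes.loc[kept.index]

    pairwise_correlations(comp_z).to_csv(outdir / "part_correlations.csv")

    # ---- stage: network --------------------------------------------------
    networks = {}
    for method in config.network_methods:
        net = infer_network(
            comp_z,
            method=method,
            stars_kwargs=dict(
                n_subsamples=config.stars_subsamples,
                threshold=config.stars_threshold,
                seed=config.seed,
            ),
        )
        net.edges.to_csv(outdir / f"network_{method}.csv", index=False)
        if net.stability_path is not None:
            net.stability_path.to_csv(outdir / f"stars_path_{method}.csv", index=False)
        networks[method] = net
        log.info("network[%s]: %d edges at penalty %.4g", method, len(net.edges), net.penalty)

    # ---- stage: srda -----------------------------------------------------
    lrs = all_pairwise_logratios(comp_z)
    trace = srda_select(lrs, target_fraction=1.0)
    trace.to_csv(outdir / "srda_trace.csv")
    k_sel = int((trace.steps["cumulative"] >= config.srda_target_fraction).idxmax()) + 1
    selected_pairs = trace.selected_pairs[:k_sel]
    log.info("srda: %d steps total, %d reach %.0f%%", len(trace.steps), k_sel,
             100 * config.srda_target_fraction)

    results = {"logcontrast": {}, "logratio_ols": {}, "r2_comparison": {}}
    if outcomes is not None:
        for name in config.outcomes:
            y = outcomes[name]
            # ---- stage: penalized log-contrast (three tiers) ------------
            tier_fits = {}
            for tier in config.tiers:
                fit = fit_with_inference(
                    comp_z, y, covariates, tier=tier,
                    n_boot=config.bootstrap_reps, seed=config.seed,
                )
                tier_fits[tier] = fit
            results["logcontrast"][name] = tier_fits
            # ---- stage: OLS on selected logratios ------------------------
            ols_fits = {}
            for tier in config.tiers:
                ols_fits[tier] = fit_logratio_ols(
                    lrs.values[selected_pairs], y, covariates, tier=tier
                )
            results["logratio_ols"][name] = ols_fits
            results["r2_comparison"][name] = compare_r2(
                lrs, lrs.values[selected_pairs], y, covariates,
                tier=max(config.tiers),
            )
            log.info("outcome[%s]: fitted %d tiers", name, len(config.tiers))
        _write_coefficient_tables(results, outdir)

    _write_report(config, outdir, trace, selected_pairs, networks, results,
                  n_kept=len(kept), n_excluded=len(exclusions), n_zero=n_zero)
    return outdir


def _write_coefficient_tables(results: dict, outdir: Path) -> None:
    rows = []
    for outcome, tier_fits in results["logcontrast"].items():
        for tier, fit in tier_fits.items():
            tab = fit.ci.reset_index(names="term")
            tab.insert(0, "outcome", outcome)
            tab.insert(1, "tier", tier)
            rows.append(tab)
    if rows:
        pd.concat(rows).to_csv(outdir / "logcontrast_coefficients.csv", index=False)
    rows = []
    for outcome, tier_fits in results["logratio_ols"].items():
        for tier, fit in tier_fits.items():
            tab = fit.tidy()
            tab.insert(0, "outcome", outcome)
            tab.insert(1, "tier", tier)
            rows.append(tab)
    if rows:
        pd.concat(rows).to_csv(outdir / "logratio_ols_coefficients.csv", index=False)


def _write_report(config, outdir, trace, selected_pairs, networks, results,
                  n_kept, n_excluded, n_zero) -> None:
    lines = ["# lymphocoda pipeline report", ""]
    lines += [
        f"- subjects analysed: {n_kept} (excluded: {n_excluded})",
        f"- zero cells replaced: {n_zero}",
        f"- seed: {config.seed}",
        "",
        "## Conditional-dependence networks",
        "",
    ]
    for method, net in networks.items():
        lines.append(f"### {method} (penalty {net.penalty:.4g})")
        lines.append("")
        if len(net.edges):
            lines.append("| i | j | sign | weight |")
            lines.append("|---|---|------|--------|")
            for _, r in net.edges.iterrows():
                lines.append(f"| {r['i']} | {r['j']} | {'+' if r['sign'] > 0 else '-'} | {r['weight']:.3f} |")
        else:
            lines.append("(no edges at the selected penalty)")
        lines.append("")
    lines += [
        "## Stepwise logratio selection",
        "",
        f"total logratio variance: {trace.total_variance:.4f}",
        "",
        "| step | logratio | additional % | cumulative % |",
        "|------|----------|--------------|--------------|",
    ]
    for _, r in trace.steps.iterrows():
        lines.append(
            f"| {int(r['step'])} | {r['pair']} | {100 * r['additional']:.1f} | {100 * r['cumulative']:.1f} |"
        )
    lines += ["", f"selected (target {100 * config.srda_target_fraction:.0f}%): "
              + ", ".join(selected_pairs), ""]
    for outcome, tier_fits in results.get("logcontrast", {}).items():
        lines += [f"## Penalized log-contrast: {outcome}", ""]
        for tier, fit in tier_fits.items():
            nz = fit.beta[fit.beta != 0]
            lines.append(
                f"- model {tier}: lambda {fit.lam:.4g}, "
                f"{len(nz)} active parts: "
                + (", ".join(f"{k} {v:+.3f}" for k, v in nz.items()) or "none")
            )
        cmp = results["r2_comparison"].get(outcome)
        if cmp:
            lines.append(
                f"- adjusted R² (selected {len(selected_pairs)} logratios vs all pairs): "
                f"{cmp['adj_r2_selected']:.3f} vs {cmp['adj_r2_full']:.3f}"
            )
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
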