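"""Experiment orchestration: scaling runs, controls, and reports.

A scaling run fits the tuning-only, coupling-only and full models at a
ladder of population sizes, drawing one random neuron subset per
(size, replicate) and reusing it — together with one trial-fold
assignment — across all three variants so that accuracy comparisons are
paired.  Controls rerun the same pipeline on within-condition shuffled
counts (noise correlations destroyed, stimulus correlations kept) and on
counts resimulated from the fitted tuning curves (conditionally
independent by construction).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .basis import BasisSpec
from .data import CovariateTable, SpikeCounts
from .glm import (
    build_design,
    cv_folds,
    fit_glm,
    penalty_path,
    poisson_log_likelihood,
    select_penalty,
)
from .metrics import ScalingCurve, fraction_variance_tuning
from .simulate import shuffle_within_condition, simulate_from_tuning_model

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "cv_accuracy_bits",
    "run_scaling_experiment",
    "run_controls",
    "write_metric_tables",
    "make_report",
]

log = logging.getLogger("popglm")

LOG2 = np.log(2.0)
VARIANTS = ("tuning", "coupling", "full")


@dataclass
class ExperimentConfig:
    """Settings of one scaling/control run."""

    basis_kind: str = "cosine_direction"
    subset_sizes: tuple[int, ...] = (1, 2, 4, 8, 16)
    replicates: int = 10
    n_folds: int = 10
    penalty_points: int = 30
    penalty_decades: float = 4.0
    variants: tuple[str, ...] = VARIANTS
    seed: int = 0

    def validate(self, n_neurons: int) -> None:
        if any(s > n_neurons for s in self.subset_sizes):
            raise ValueError(
                f"subset sizes {self.subset_sizes} exceed population size "
                f"{n_neurons}"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class RunManifest:
    """Provenance of one run: config hash, seeds, version, timings."""

    config_hash: str
    seed: int
    software_version: str = __version__
    status: str = "running"
    timings: dict = field(default_factory=dict)
    warnings_count: int = 0

    @staticmethod
    def for_config(config) -> "RunManifest":
        blob = json.dumps(asdict(config), sort_keys=True, default=str)
        h = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return RunManifest(config_hash=h, seed=config.seed)

    def write(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def cv_accuracy_bits(
    y: np.ndarray,
    design,
    variant: str,
    bin_duration: float,
    n_folds: int = 10,
    seed: int = 0,
    penalty_grid: np.ndarray | None = None,
    basis_spec: BasisSpec | None = None,
) -> tuple[float, float]:
    """CV spike-prediction accuracy (bits/s) with CV-selected penalty.

    Selects the L1 penalty on the same folds used for evaluation, then
    reports the held-out log-likelihood ratio of the selected model
    against the per-fold homogeneous null.  Returns (bits_per_s, penalty).
    """
    y = np.asarray(y, dtype=float)
    has_penalized = design.blocks_for(variant)[2].any()
    if has_penalized:
        if penalty_grid is None:
            penalty_grid = penalty_path(y, design, variant, basis_spec=basis_spec)
        lam, cv_ll = select_penalty(
            y, design, variant, penalty_grid, n_folds, seed, basis_spec=basis_spec
        )
        chosen = int(np.argmin(np.abs(np.asarray(penalty_grid) - lam)))
        ll_model = float(cv_ll[chosen]) * len(y)
    else:
        lam = 0.0
        lam_, cv_ll = select_penalty(
            y, design, variant, np.array([0.0]), n_folds, seed, basis_spec=basis_spec
        )
        ll_model = float(cv_ll[0]) * len(y)
    ll_null = 0.0
    for train, test in cv_folds(len(y), n_folds, seed):
        rate = max(y[train].mean(), 1e-12)
        ll_null += poisson_log_likelihood(y[test], np.full(len(test), rate))
    bits = (ll_model - ll_null) / LOG2 / (len(y) * bin_duration)
    return bits, lam


def run_scaling_experiment(
    data: SpikeCounts,
    covariates: CovariateTable | None,
    basis_spec: BasisSpec | None,
    config: ExperimentConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Accuracy and variance-fraction curves versus population size.

    For each size and replicate a random neuron subset is drawn once and
    shared across variants; folds are shared too, so differences between
    variants are paired.  Returns a dict with the tidy per-fit table
    (``records``) and one ScalingCurve per variant (``curves``), plus the
    full-model FVE curve (``fve_curve``).
    """
    config.validate(data.n_neurons)
    manifest = RunManifest.for_config(config)
    outpath = Path(outdir) if outdir is not None else None
    if outpath is not None:
        manifest.write(outpath)
    t_start = time.time()
    rng = np.random.default_rng(config.seed)
    rows = []
    n_fail = n_total = 0
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for size in config.subset_sizes:
            for rep in range(config.replicates):
                subset = np.sort(
                    rng.choice(data.n_neurons, size=size, replace=False)
                )
                fold_seed = int(rng.integers(2**31 - 1))
                for target in subset:
                    design = build_design(
                        data, covariates, basis_spec, int(target), subset
                    )
                    y = data.counts[:, target]
                    row = {"size": size, "replicate": rep, "neuron": int(target)}
                    for variant in config.variants:
                        n_total += 1
                        try:
                            bits, lam = cv_accuracy_bits(
                                y, design, variant, data.bin_duration,
                                config.n_folds, fold_seed, basis_spec=basis_spec,
                            )
                            rec = dict(row)
                            rec.update(
                                variant=variant, accuracy_bits=bits, penalty=lam
                            )
                            if variant == "full":
                                full_fit = fit_glm(
                                    y, design, "full", lam, basis_spec=basis_spec
                                )
                                rec["fve"] = fraction_variance_tuning(
                                    full_fit, design
                                )
                            rows.append(rec)
                        except Exception as exc:
                            n_fail += 1
                            log.warning(
                                "fit failed (size=%d rep=%d neuron=%d %s): %s",
                                size, rep, target, variant, exc,
                            )
        manifest.warnings_count = len(caught)
    if n_total and n_fail > 0.1 * n_total:
        manifest.status = "failed"
        if outpath is not None:
            manifest.write(outpath)
        raise RuntimeError(
            f"{n_fail}/{n_total} fits failed (>10%); aborting run"
        )
    records = pd.DataFrame(rows)
    curves = {}
    for variant in config.variants:
        sub = records[records["variant"] == variant]
        means = sub.groupby("size")["accuracy_bits"].mean()
        sems = sub.groupby("size")["accuracy_bits"].sem().fillna(0.0)
        curves[variant] = ScalingCurve(
            sizes=means.index.to_numpy(),
            values=means.to_numpy(),
            sem=sems.to_numpy(),
        ).fit()
    fve_curve = None
    if "full" in config.variants:
        sub = records[records["variant"] == "full"]
        means = sub.groupby("size")["fve"].mean()
        sems = sub.groupby("size")["fve"].sem().fillna(0.0)
        fve_curve = ScalingCurve(
            sizes=means.index.to_numpy(),
            values=means.to_numpy(),
            sem=sems.to_numpy(),
        )
    manifest.status = "complete"
    manifest.timings["scaling_s"] = round(time.time() - t_start, 2)
    result = {"records": records, "curves": curves, "fve_curve": fve_curve,
              "manifest": manifest}
    if outpath is not None:
        records.to_csv(outpath / "scaling_records.tsv", sep="\t", index=False)
        _write_curves(outpath / "scaling_curves.tsv", curves, fve_curve)
        manifest.write(outpath)
    return result


def _write_curves(path: Path, curves: dict, fve_curve) -> None:
    rows = []
    for variant, c in curves.items():
        for s, v, e in zip(c.sizes, c.values, c.sem):
            rows.append(
                {"metric": "accuracy_bits", "variant": variant, "size": int(s),
                 "mean": v, "sem": e}
            )
    if fve_curve is not None:
        for s, v, e in zip(fve_curve.sizes, fve_curve.values, fve_curve.sem):
            rows.append(
                {"metric": "fve", "variant": "full", "size": int(s),
                 "mean": v, "sem": e}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_controls(
    data: SpikeCounts,
    covariates: CovariateTable | None,
    basis_spec: BasisSpec | None,
    config: ExperimentConfig,
    outdir: str | Path | None = None,
    arms: tuple[str, ...] = ("shuffled", "independent"),
) -> dict:
    """Shuffle and independent-resimulation controls.

    ``shuffled``: within-condition shuffling destroys noise correlations;
    any full-model accuracy advantage over tuning should collapse.
    ``independent``: counts resimulated from fitted tuning-only models are
    conditionally independent; the fraction of variance explained by
    tuning in a refitted full model should stay near 1.
    Each arm produces the same tables as the main run, flagged by arm.
    """
    out: dict = {}
    for arm in arms:
        if arm == "shuffled":
            if data.condition_labels is None:
                raise ValueError("shuffle control requires condition labels")
            arm_data = shuffle_within_condition(data, seed=config.seed + 1)
        elif arm == "independent":
            tc_fits = []
            for target in range(data.n_neurons):
                design = build_design(data, covariates, basis_spec, target, None)
                tc_fits.append(
                    fit_glm(
                        data.counts[:, target], design, "tuning",
                        basis_spec=basis_spec,
                    )
                )
            arm_data = simulate_from_tuning_model(
                tc_fits, covariates, seed=config.seed + 2,
                bin_duration=data.bin_duration,
                condition_labels=data.condition_labels,
            )
        else:
            raise ValueError(f"unknown control arm {arm!r}")
        arm_out = Path(outdir) / arm if outdir is not None else None
        out[arm] = run_scaling_experiment(
            arm_data, covariates, basis_spec, config, arm_out
        )
        out[arm]["data"] = arm_data
    return out


def write_metric_tables(
    data: SpikeCounts,
    covariates: CovariateTable | None,
    basis_spec: BasisSpec | None,
    outdir: str | Path,
    seed: int = 0,
) -> None:
    """Per-neuron and per-pair metric tables for the report panels.

    ``neurons.tsv``: tuning modulation (Hz) and preference under the
    tuning-only and full models, plus in/out degree.  ``pairs.tsv``:
    tuning overlap, spike-count correlation and fitted coupling strength
    (mean |beta| of the two directions) for every neuron pair.
    """
    from .metrics import (
        degree_summary,
        spike_count_correlation,
        tuning_modulation,
        tuning_overlap,
        tuning_preference,
    )
    from .glm import fit_population

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tc = fit_population(data, covariates, basis_spec, "tuning", seed=seed,
                        penalty=0.0)
    full = fit_population(data, covariates, basis_spec, "full", seed=seed,
                          penalty="cv")
    net = degree_summary(full, data)
    rows = []
    for t, f in zip(tc, full):
        if t is None or f is None:
            continue
        k = int(np.flatnonzero(net.neurons == f.neuron)[0])
        rows.append(
            {
                "neuron": f.neuron,
                "modulation_tc_hz": tuning_modulation(t, basis_spec, data.bin_duration),
                "modulation_full_hz": tuning_modulation(f, basis_spec, data.bin_duration),
                "preference_tc": tuning_preference(t, basis_spec),
                "preference_full": tuning_preference(f, basis_spec),
                "in_degree": int(net.in_degree[k]),
                "out_degree": int(net.out_degree[k]),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "neurons.tsv", sep="\t", index=False)
    corr = spike_count_correlation(data)
    pairs = []
    for a in range(data.n_neurons):
        for b in range(a + 1, data.n_neurons):
            ta, tb = tc[a], tc[b]
            if ta is None or tb is None:
                continue
            W = net.coupling_matrix
            pairs.append(
                {
                    "i": a, "j": b,
                    "overlap": tuning_overlap(ta.tuning_weights, tb.tuning_weights),
                    "correlation": corr[a, b],
                    "coupling_strength": 0.5 * (abs(W[a, b]) + abs(W[b, a])),
                }
            )
    pd.DataFrame(pairs).to_csv(outdir / "pairs.tsv", sep="\t", index=False)


def _slope_with_ci(x, y):
    """OLS slope and 95% CI, ignoring missing pairs."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    res = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
    lo, hi = res.conf_int()[1]
    return float(res.params[1]), float(lo), float(hi)


def make_report(run_dir: str | Path, out_name: str = "report") -> Path:
    """Plot the tables a scaling/control run wrote; embed the manifest.

    Produces ``<run_dir>/<out_name>.png`` (accuracy and FVE versus size)
    and ``<out_name>.md`` summarising curves and the manifest.  Raises if
    the run directory has no curves table.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    curves_path = run_dir / "scaling_curves.tsv"
    if not curves_path.exists():
        raise FileNotFoundError(
            f"no scaling_curves.tsv in {run_dir}; run `scaling` first"
        )
    curves = pd.read_csv(curves_path, sep="\t")
    manifest_path = run_dir / "manifest.yaml"
    manifest = (
        yaml.safe_load(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    neurons_path = run_dir / "neurons.tsv"
    pairs_path = run_dir / "pairs.tsv"
    have_tables = neurons_path.exists() and pairs_path.exists()
    n_rows = 2 if have_tables else 1
    fig, axes = plt.subplots(n_rows, 3, figsize=(13, 4 * n_rows), squeeze=False)
    acc = curves[curves["metric"] == "accuracy_bits"]
    colors = {"tuning": "k", "coupling": "tab:blue", "full": "tab:red"}
    for variant, sub in acc.groupby("variant"):
        axes[0, 0].errorbar(
            sub["size"], sub["mean"], yerr=sub["sem"], label=variant,
            color=colors.get(variant), marker="o",
        )
    axes[0, 0].set_xlabel("neurons in model")
    axes[0, 0].set_ylabel("spike prediction accuracy (bits/s)")
    axes[0, 0].legend()
    fve = curves[curves["metric"] == "fve"]
    if len(fve):
        axes[0, 1].errorbar(
            fve["size"], fve["mean"], yerr=fve["sem"], color="tab:red",
            marker="o",
        )
        axes[0, 1].set_ylim(0, 1.05)
        axes[0, 1].set_xlabel("neurons in model")
        axes[0, 1].set_ylabel("fraction of variance explained by tuning")
    axes[0, 2].axis("off")
    slope_line = ""
    if have_tables:
        neurons = pd.read_csv(neurons_path, sep="\t")
        pairs = pd.read_csv(pairs_path, sep="\t")
        ax = axes[0, 2]
        ax.axis("on")
        bins = np.arange(-0.5, neurons[["in_degree", "out_degree"]].max().max() + 1.5)
        ax.hist(neurons["in_degree"], bins=bins, alpha=0.6, color="tab:blue",
                label="in-degree")
        ax.hist(neurons["out_degree"], bins=bins, alpha=0.6, color="tab:red",
                label="out-degree")
        ax.set_xlabel("degree")
        ax.set_ylabel("neurons")
        ax.legend()
        ax = axes[1, 0]
        lim = max(neurons["modulation_tc_hz"].max(), 1e-9) * 1.05
        ax.scatter(neurons["modulation_tc_hz"], neurons["modulation_full_hz"],
                   s=12, color="tab:red")
        ax.plot([0, lim], [0, lim], color="gray", lw=0.8)
        ax.set_xlabel("modulation, tuning model (Hz)")
        ax.set_ylabel("modulation, full model (Hz)")
        ax = axes[1, 1]
        ax.scatter(pairs["overlap"], pairs["correlation"], s=10,
                   color="tab:blue")
        ax.set_xlabel("tuning overlap")
        ax.set_ylabel("spike count correlation")
        ax = axes[1, 2]
        ax.scatter(pairs["overlap"], pairs["coupling_strength"], s=10,
                   color="tab:red")
        slope, lo, hi = _slope_with_ci(
            pairs["overlap"], pairs["coupling_strength"]
        )
        slope_line = (
            f"overlap-vs-coupling slope: {slope:.4f} "
            f"(95% CI [{lo:.4f}, {hi:.4f}])"
        )
        ax.set_title(slope_line, fontsize=8)
        ax.set_xlabel("tuning overlap")
        ax.set_ylabel("coupling strength |beta|")
    fig.tight_layout()
    png = run_dir / f"{out_name}.png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    md = run_dir / f"{out_name}.md"
    with open(md, "w") as fh:
        fh.write("# Scaling run report\n\n")
        fh.write(f"![curves]({png.name})\n\n## Curves\n\n")
        fh.write(curves.to_markdown(index=False))
        if have_tables:
            fh.write("\n\n## Degrees\n\n")
            fh.write(
                pd.read_csv(neurons_path, sep="\t")[
                    ["neuron", "in_degree", "out_degree"]
                ].to_markdown(index=False)
            )
            fh.write(f"\n\n{slope_line}\n")
        fh.write("\n\n## Manifest\n\n```yaml\n")
        fh.write(yaml.safe_dump(manifest, sort_keys=False))
        fh.write("```\n")
    return md
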