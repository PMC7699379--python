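"""End-to-end orchestration of the synthetic induction study.

``run_study`` reproduces the study flow on generated data: simulate gait
and pain scores, quantify movement asymmetry from the trajectories,
truncate each horse's data at its maximum total asymmetry score, then run
the three analyses (inter-observer reliability, lasso item selection,
MCA plus dimension regression) and write every intermediate artifact so a
run is fully auditable and reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import mca as mca_mod
from . import reliability as rel
from . import selection as sel
from .scales import ScaleItem, load_scales
from .synth import GaitParams, default_design, simulate_gait, simulate_scores

__all__ = ["StudyConfig", "RunSummary", "run_study", "report"]


@dataclass
class StudyConfig:
    """Serializable configuration of a full synthetic study run."""

    seed: int = 0
    # trial structure
    n_horses: int = 8
    n_observers_per_assessment: int = 3
    occasions_per_horse: int = 5
    second_trot_prob: float = 0.25
    observer_noise_sd: float = 1.0
    horse_effect_sd: float = 0.3
    # gait simulation
    stride_frequency: float = 1.3
    n_strides: int = 20
    sampling_rate: float = 200.0
    base_amplitude_mm: float = 40.0
    noise_sd_mm: float = 2.0
    pelvis_fraction: float = 0.75
    baseline_total_mm_mean: float = 4.0
    baseline_total_mm_sd: float = 2.0
    # kinematics
    cutoff_multiplier: float = 6.0
    prominence_fraction: float = 0.2
    # selection
    n_folds: int = 10
    per_scale: bool = False
    # mca
    min_fraction: float = 0.01
    p_threshold: float = 0.01
    row_mode: str = "observer"
    # latent item effects as "SCALE:item" -> effect size; None = generator
    # defaults, {} = null study (no item carries signal)
    item_effects: dict[str, float] | None = None

    def validate(self) -> None:
        if not 0 < self.pelvis_fraction < 1:
            raise ValueError("pelvis_fraction must lie in (0, 1)")
        if self.row_mode not in ("observer", "assessment"):
            raise ValueError("row_mode must be 'observer' or 'assessment'")
        if self.occasions_per_horse < 4:
            raise ValueError("need baseline plus at least 3 post-induction occasions")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class RunSummary:
    """Traceable headline numbers of one study run."""

    config: dict
    per_horse_max: dict[str, dict]
    n_measurements: int
    n_assessments: int
    n_strides_dropped: int
    reliability: pd.DataFrame
    selected_items: list[tuple[str, float]]
    selected_effects: list[tuple[str, float]]
    per_scale_items: dict[str, list[tuple[str, float]]]
    included_dims: list[int]
    significant_dims: list[int]
    dim_regression: mca_mod.DimensionRegression | None
    dim_interpretations: dict[int, list[dict]]
    degenerate_items: list[str]
    fold_seed: int


def _simulate_measurements(config: StudyConfig, design, out_dir: Path):
    """Generate trajectories, run the kinematic chain, and assemble the
    per-measurement asymmetry table (with the change-from-baseline score)."""
    rng = np.random.default_rng(config.seed + 500)
    traj_dir = out_dir / "trajectories"
    traj_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    dropped = 0
    for hi, horse in enumerate(design.horses):
        side = -1.0 if design.induced_side[horse] == "left" else 1.0
        baseline_total = max(0.5, rng.normal(config.baseline_total_mm_mean,
                                             config.baseline_total_mm_sd))
        stride_f = config.stride_frequency + rng.uniform(-0.1, 0.1)
        traj = design.asymmetry_trajectory[horse]
        for oi, occ in enumerate(design.occasions):
            n_repeats = 1
            if oi > 0 and rng.random() < config.second_trot_prob:
                n_repeats = 2
            for ri in range(1, n_repeats + 1):
                total = baseline_total + traj[oi] * (1.0 + 0.08 * (ri - 1))
                params = GaitParams(
                    stride_frequency=stride_f,
                    n_strides=config.n_strides,
                    sampling_rate=config.sampling_rate,
                    head_asym_mm=side * 2 * (1 - config.pelvis_fraction) * total,
                    pelvis_asym_mm=side * config.pelvis_fraction * total,
                    base_amplitude_mm=config.base_amplitude_mm,
                    noise_sd_mm=config.noise_sd_mm,
                    seed=int(config.seed + 100_000 + 1000 * hi + 10 * oi + ri),
                )
                trj = simulate_gait(params)
                trj.to_frame().to_csv(
                    traj_dir / f"trajectories_{horse}_{occ}_r{ri}.csv",
                    index=False, float_format="%.4f",
                )
                m = kin.measure_asymmetry(
                    trj,
                    cutoff_multiplier=config.cutoff_multiplier,
                    prominence_fraction=config.prominence_fraction,
                )
                dropped += m.n_strides_dropped
                rows.append(
                    {
                        "horse": horse,
                        "occasion": occ,
                        "repeat": ri,
                        "hd_min_mm": m.hd_min_mm,
                        "pd_min_mm": m.pd_min_mm,
                        "total_asymmetry_mm": m.total_asymmetry_mm,
                        "n_strides_used": m.n_strides_used,
                    }
                )
    asym = pd.DataFrame(rows)
    base = asym[(asym["occasion"] == "b0") & (asym["repeat"] == 1)].set_index("horse")[
        "total_asymmetry_mm"
    ]
    asym["score_mm"] = asym["total_asymmetry_mm"] - asym["horse"].map(base)
    return asym, dropped


def _responses_for_keys(keys: pd.DataFrame, asym: pd.DataFrame) -> np.ndarray:
    lookup = {k: g for k, g in asym.groupby(["horse", "occasion"])}
    out = np.full(len(keys), np.nan)
    for i, row in enumerate(keys.itertuples(index=False)):
        grp = lookup.get((row.horse, row.occasion))
        if grp is not None:
            out[i] = sel._pair_scores(row.phase, grp)
    return out


def run_study(config: StudyConfig, out_dir: str | Path) -> RunSummary:
    """Execute all study stages, writing each artifact under ``out_dir``.

    Stages: simulate -> kinematics -> truncate/pair -> reliability ->
    lasso -> MCA + dimension regression -> summary/report.  Per-horse data
    are truncated at the occasion of maximum total asymmetry score before
    any statistical analysis.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    scales = load_scales()
    kwargs = {}
    if config.item_effects is not None:
        kwargs["item_effects"] = {
            tuple(k.split(":", 1)): v for k, v in config.item_effects.items()
        }
    design = default_design(
        seed=config.seed,
        n_horses=config.n_horses,
        n_observers_per_assessment=config.n_observers_per_assessment,
        occasions_per_horse=config.occasions_per_horse,
        observer_noise_sd=config.observer_noise_sd,
        horse_effect_sd=config.horse_effect_sd,
        second_trot_prob=config.second_trot_prob,
        **kwargs,
    )

    # --- gait + kinematics -------------------------------------------------
    asym, n_dropped = _simulate_measurements(config, design, out)
    asym.to_csv(out / "asymmetry.csv", index=False, float_format="%.6f")

    # --- pain scores -------------------------------------------------------
    scores, truth = simulate_scores(design, scales)
    scores.to_csv(out / "scores.csv", index=False)
    (out / "truth.json").write_text(
        json.dumps(
            {
                "item_effects": {f"{s}:{i}": v for (s, i), v in truth.item_effects.items()},
                "asymmetry_trajectory": truth.asymmetry_trajectory,
                "induced_side": truth.induced_side,
                "normalization_mm": truth.normalization_mm,
                "observer_assignment": truth.observer_assignment,
                "seed": truth.seed,
            },
            indent=2, sort_keys=True,
        )
    )

    # --- truncation at per-horse maximum score -----------------------------
    asym_trunc = sel.truncate_at_max_score(asym)
    kept = set(map(tuple, asym_trunc[["horse", "occasion"]].drop_duplicates().to_numpy()))
    scores_kept = scores[
        [(h, o) in kept for h, o in zip(scores["horse"], scores["occasion"])]
    ].reset_index(drop=True)
    per_horse_max = {}
    for horse, grp in asym.groupby("horse"):
        idx = grp["score_mm"].idxmax()
        per_horse_max[horse] = {
            "occasion": str(grp.loc[idx, "occasion"]),
            "max_score_mm": float(grp.loc[idx, "score_mm"]),
        }

    # --- reliability -------------------------------------------------------
    rel_results = rel.reliability_report(scores_kept, scales)
    rel_table = rel.reliability_table(rel_results)
    rel_table.to_csv(out / "reliability.csv", index=False, float_format="%.6g")

    # --- lasso selection ---------------------------------------------------
    design_all = sel.build_design(scores_kept, asym_trunc, scales, truncate=True)
    fit = sel.fit_lasso_cv(design_all, n_folds=config.n_folds, seed=config.seed)
    selection = sel.select_items(fit, design_all)
    per_scale_items: dict[str, list[tuple[str, float]]] = {}
    if config.per_scale:
        for scale_id in ("HGS", "EQUUS_FAP", "EPS", "CPS"):
            sub = scores_kept[scores_kept["scale"] == scale_id]
            d = sel.build_design(sub, asym_trunc, scales, truncate=True)
            f = sel.fit_lasso_cv(d, n_folds=config.n_folds, seed=config.seed)
            per_scale_items[scale_id] = sel.select_items(f, d).items
    (out / "lasso.json").write_text(
        json.dumps(
            {
                "lambda_path": fit.lambda_path.tolist(),
                "cv_mean_error": fit.cv_mean_error.tolist(),
                "cv_se": fit.cv_se.tolist(),
                "lambda_min": fit.lambda_min,
                "intercept": fit.intercept,
                "coefficients": fit.coefficients,
                "selected_items": selection.items,
                "selected_effects": selection.effects,
                "per_scale_items": per_scale_items,
                "n_folds": fit.n_folds,
                "fold_seed": fit.seed,
            },
            indent=2, sort_keys=True,
        )
    )

    # --- MCA + dimension regression ---------------------------------------
    indicator = mca_mod.build_indicator(scores_kept, scales, row_mode=config.row_mode)
    mca = mca_mod.fit_mca(indicator)
    dims = mca_mod.select_dims(mca, min_fraction=config.min_fraction)
    responses = _responses_for_keys(indicator.row_keys, asym_trunc)
    ok = np.isfinite(responses)
    horse_arr = indicator.row_keys["horse"].to_numpy()[ok]
    obs_arr = (
        indicator.row_keys["observer"].to_numpy()[ok]
        if "observer" in indicator.row_keys.columns
        else None
    )
    regression = mca_mod.regress_dims(
        mca.row_coords.loc[ok],
        responses[ok],
        included_dims=dims,
        horse=horse_arr,
        observer=obs_arr,
        p_threshold=config.p_threshold,
    )
    interpretations = {
        d: mca_mod.interpret_dim(mca, regression, d) for d in regression.significant_dims
    }
    (out / "mca.json").write_text(
        json.dumps(
            {
                "eigenvalues": mca.eigenvalues.tolist(),
                "explained_fraction": mca.explained_fraction.tolist(),
                "total_inertia": mca.total_inertia,
                "included_dims": regression.included_dims,
                "retained_dims": regression.retained_dims,
                "regression": {
                    str(d): {
                        "beta": regression.betas[d],
                        "se": regression.ses[d],
                        "z": regression.z_values[d],
                        "p": regression.p_values[d],
                    }
                    for d in regression.retained_dims
                },
                "significant_dims": regression.significant_dims,
                "random_effect_variances": regression.random_effect_variances,
                "engine": regression.engine,
                "lag1_autocorr": regression.lag1_autocorr,
                "interpretations": {str(d): v for d, v in interpretations.items()},
            },
            indent=2, sort_keys=True,
        )
    )

    summary = RunSummary(
        config=asdict(config),
        per_horse_max=per_horse_max,
        n_measurements=len(asym),
        n_assessments=int(
            scores[["horse", "occasion", "phase"]].drop_duplicates().shape[0]
        ),
        n_strides_dropped=n_dropped,
        reliability=rel_table,
        selected_items=selection.items,
        selected_effects=selection.effects,
        per_scale_items=per_scale_items,
        included_dims=regression.included_dims,
        significant_dims=regression.significant_dims,
        dim_regression=regression,
        dim_interpretations=interpretations,
        degenerate_items=indicator.degenerate_items,
        fold_seed=fit.seed,
    )
    (out / "summary.json").write_text(
        json.dumps(
            {
                "per_horse_max": summary.per_horse_max,
                "n_measurements": summary.n_measurements,
                "n_assessments": summary.n_assessments,
                "n_strides_dropped": summary.n_strides_dropped,
                "selected_items": summary.selected_items,
                "significant_dims": summary.significant_dims,
                "degenerate_items": summary.degenerate_items,
                "fold_seed": summary.fold_seed,
                "seed": config.seed,
            },
            indent=2, sort_keys=True,
        )
    )
    (out / "report.md").write_text(report(summary))
    return summary


def report(summary: RunSummary) -> str:
    """Render a human-readable markdown report of a study run."""
    lines = ["# Synthetic induction study report", ""]
    lines.append("## Per-horse maximum total asymmetry score")
    lines.append("")
    lines.append("| horse | occasion | max score (mm) |")
    lines.append("|---|---|---|")
    for horse in sorted(summary.per_horse_max):
        rec = summary.per_horse_max[horse]
        lines.append(f"| {horse} | {rec['occasion']} | {rec['max_score_mm']:.1f} |")
    lines.append("")
    lines.append(
        f"Measurements: {summary.n_measurements}; assessments: "
        f"{summary.n_assessments}; strides dropped: {summary.n_strides_dropped}."
    )
    lines.append("")
    lines.append("## Inter-observer reliability (Kendall's W)")
    lines.append("")
    lines.append("| scale | item | n | W | p | band |")
    lines.append("|---|---|---|---|---|---|")
    for row in summary.reliability.itertuples(index=False):
        if row.degenerate:
            lines.append(f"| {row.scale} | {row.item} | {row.n} | — | — | degenerate |")
        else:
            lines.append(
                f"| {row.scale} | {row.item} | {row.n} | {row.W:.3f} "
                f"| {row.p:.3g} | {row.band} |"
            )
    lines.append("")
    lines.append("## Lasso-selected items (lambda_min)")
    lines.append("")
    if summary.selected_items:
        for col, coef in summary.selected_items:
            lines.append(f"- `{col}`: {coef:+.3f}")
    else:
        lines.append("no items selected")
    lines.append("")
    lines.append("## Significant MCA dimensions (p < threshold)")
    lines.append("")
    reg = summary.dim_regression
    if reg is not None and reg.retained_dims:
        lines.append("| dim | beta | SE | z | p |")
        lines.append("|---|---|---|---|---|")
        for d in reg.retained_dims:
            star = " *" if d in reg.significant_dims else ""
            lines.append(
                f"| {d}{star} | {reg.betas[d]:.2f} | {reg.ses[d]:.2f} "
                f"| {reg.z_values[d]:.2f} | {reg.p_values[d]:.3g} |"
            )
    else:
        lines.append("no dimensions retained")
    lines.append("")
    if summary.degenerate_items:
        lines.append(
            "Degenerate (single-level) categories: "
            + ", ".join(summary.degenerate_items)
        )
        lines.append("")
    return "\n".join(lines)
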