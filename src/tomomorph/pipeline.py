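"""Pipeline orchestration: metrics -> persistence -> distances -> null
-> statistics over conditions of one or more tomograms, with
machine-readable outputs and seed/config provenance."""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .errors import EstimationError, TomomorphError, ValidationError
from .metrics import DensityResult, cytosolic_fibril_density
from .persistence import PersistenceFit, fit_persistence_length, tangent_correlation
from .scene import Fibril, TomogramScene, filter_fibrils, resample_polyline
from .spatial import (
    BandSummary,
    DistanceProfile,
    EnsembleKSResult,
    KSResult,
    NullEnsemble,
    band,
    ensemble_ks_test,
    fibril_membrane_distances,
    inter_membrane_distances,
    ks_compare,
    membrane_distance_field,
    null_ensemble,
)

logger = logging.getLogger(__name__)


@dataclass
class TomogramInput:
    """One tomogram: a scene plus its traced fibrils."""

    scene: TomogramScene
    fibrils: list[Fibril]

    @property
    def tomogram_id(self) -> str:
        return self.scene.tomogram_id


@dataclass
class AnovaResult:
    F: float
    pvalue: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    pairwise_welch: dict[str, float]  # "a|b" -> p (Welch t-test, two-sided)


def anova_densities(groups: dict[str, list[float]]) -> AnovaResult:
    """One-way ANOVA on per-tomogram density values grouped by condition."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 tomograms")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled, pooled[0]):
        raise EstimationError("all density values identical: zero variance")
    F, p = stats.f_oneway(*arrays.values())
    pairwise = {}
    for a, b in itertools.combinations(sorted(arrays), 2):
        t = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
        pairwise[f"{a}|{b}"] = float(t.pvalue)
    return AnovaResult(
        F=float(F),
        pvalue=float(p),
        group_means={k: float(v.mean()) for k, v in arrays.items()},
        group_sizes={k: int(v.size) for k, v in arrays.items()},
        pairwise_welch=pairwise,
    )


@dataclass
class TomogramReport:
    tomogram_id: str
    lengths: np.ndarray
    density: DensityResult
    fibril_membrane_profile: DistanceProfile | None
    fibril_membrane_sample: np.ndarray | None
    inter_membrane_profile: DistanceProfile | None
    null: NullEnsemble | None
    distances_applicable: bool


@dataclass
class ConditionSummary:
    """Everything computed for one experimental condition."""

    condition: str
    tomogram_reports: list[TomogramReport]
    densities: list[DensityResult]
    pooled_lengths: np.ndarray
    persistence: PersistenceFit | None
    correlation: "object | None"  # CorrelationCurve when estimable
    fibril_membrane_band: BandSummary | None
    null_band: BandSummary | None
    inter_membrane_band: BandSummary | None
    ks_fibril_membrane: KSResult | None
    ks_ensemble: EnsembleKSResult | None = None
    notes: dict = field(default_factory=dict)


def analyze_tomogram(
    tomo: TomogramInput, config: RunConfig, seed: int
) -> TomogramReport:
    """Metrics and distance statistics for a single tomogram."""
    scene, fibrils = tomo.scene, tomo.fibrils
    tid = tomo.tomogram_id
    try:
        lengths = np.array([f.length for f in fibrils])
        density = cytosolic_fibril_density(scene, fibrils)
    except TomomorphError as exc:
        raise type(exc)(f"[metrics/{tid}] {exc}") from exc

    if not scene.organelle_ids:
        return TomogramReport(
            tomogram_id=tid, lengths=lengths, density=density,
            fibril_membrane_profile=None, fibril_membrane_sample=None,
            inter_membrane_profile=None, null=None, distances_applicable=False,
        )

    try:
        field_nm = membrane_distance_field(scene)
        dense = [resample_polyline(f, scene.voxel_size) for f in fibrils]
        sample = fibril_membrane_distances(dense, field_nm, scene)
        profile = DistanceProfile.from_sample(
            sample.values, config.bin_edges, source="experimental", tomogram_id=tid
        )
    except TomomorphError as exc:
        raise type(exc)(f"[distances/{tid}] {exc}") from exc

    inter_profile = None
    if len(scene.organelle_ids) >= 2:
        inter = inter_membrane_distances(scene)
        inter_profile = DistanceProfile.from_sample(
            inter.values, config.bin_edges, source="experimental", tomogram_id=tid
        )

    try:
        ensemble = null_ensemble(
            scene, dense, field_nm, config.bin_edges,
            n_simulations=config.n_simulations, seed=seed,
            rotations=config.rotations, max_retries=config.max_retries,
        )
    except TomomorphError as exc:
        raise type(exc)(f"[null/{tid}] {exc}") from exc

    return TomogramReport(
        tomogram_id=tid, lengths=lengths, density=density,
        fibril_membrane_profile=profile, fibril_membrane_sample=sample.values,
        inter_membrane_profile=inter_profile, null=ensemble,
        distances_applicable=True,
    )


def analyze_condition(
    condition: str,
    tomograms: list[TomogramInput],
    config: RunConfig,
    seed: int,
) -> ConditionSummary:
    if not tomograms:
        raise ValidationError(f"condition {condition!r} has no tomograms")
    reports = [analyze_tomogram(t, config, seed) for t in tomograms]

    pooled_fibrils = [f for t in tomograms for f in t.fibrils]
    persistence = None
    curve = None
    notes: dict = {}
    try:
        max_sep = min(
            config.max_tangent_separation,
            max(f.length for f in pooled_fibrils) if pooled_fibrils else 0.0,
        )
        curve = tangent_correlation(pooled_fibrils, config.resample_step, max_sep)
        persistence = fit_persistence_length(
            curve, radius_nm=config.fibril_radius, temperature_K=config.temperature
        )
    except (EstimationError, ValidationError) as exc:
        notes["persistence"] = f"not estimable: {exc}"

    applicable = [r for r in reports if r.distances_applicable]
    fm_band = null_band = inter_band = ks = ks_ens = None
    if applicable:
        fm_band = band([r.fibril_membrane_profile for r in applicable])
        sim_profiles = [p for r in applicable for p in r.null.profiles]
        null_band = band(sim_profiles)
        inter_profiles = [
            r.inter_membrane_profile for r in applicable
            if r.inter_membrane_profile is not None
        ]
        if inter_profiles:
            inter_band = band(inter_profiles)
        exp_pool = np.concatenate([r.fibril_membrane_sample for r in applicable])
        sim_pool = np.concatenate([r.null.pooled_sample() for r in applicable])
        try:
            ks = ks_compare(exp_pool, sim_pool, cutoff=config.contact_cutoff)
        except TomomorphError as exc:
            notes["ks"] = f"not computed: {exc}"
        # pooled-across-tomograms per-simulation samples for the
        # exchangeability-calibrated comparison
        try:
            n_sims = min(r.null.n_simulations for r in applicable)
            per_sim = [
                np.concatenate([r.null.samples[s] for r in applicable])
                for s in range(n_sims)
            ]
            ks_ens = ensemble_ks_test(
                exp_pool, per_sim, cutoff=config.contact_cutoff
            )
        except TomomorphError as exc:
            ks_ens = None
            notes["ks_ensemble"] = f"not computed: {exc}"
    else:
        ks_ens = None
        notes["distances"] = "not applicable (no organelles in any tomogram)"

    return ConditionSummary(
        condition=condition,
        tomogram_reports=reports,
        densities=[r.density for r in reports],
        pooled_lengths=(
            np.concatenate([r.lengths for r in reports])
            if reports else np.empty(0)
        ),
        persistence=persistence,
        correlation=curve,
        fibril_membrane_band=fm_band,
        null_band=null_band,
        inter_membrane_band=inter_band,
        ks_fibril_membrane=ks,
        ks_ensemble=ks_ens,
        notes=notes,
    )


def run_pipeline(
    config: RunConfig,
    conditions: dict[str, list[TomogramInput]],
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, ConditionSummary]:
    """Full pipeline over conditions; optionally writes all outputs
    (CSV/JSON plus a JSON-lines log) under ``out_dir``."""
    seed = config.rng_seed if seed is None else seed
    summaries: dict[str, ConditionSummary] = {}
    for name, tomos in conditions.items():
        filtered = [
            TomogramInput(
                scene=t.scene,
                fibrils=filter_fibrils(t.fibrils, config.min_fibril_length),
            )
            for t in tomos
        ]
        summaries[name] = analyze_condition(name, filtered, config, seed)

    anova = None
    groups = {
        name: [d.density for d in s.densities] for name, s in summaries.items()
    }
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        try:
            anova = anova_densities(groups)
        except TomomorphError as exc:
            logger.warning("ANOVA skipped: %s", exc)

    if out_dir is not None:
        write_outputs(Path(out_dir), config, seed, summaries, anova)
    return summaries


# ---------------------------------------------------------------------------
# output writing

def _fit_to_dict(fit: PersistenceFit | None) -> dict | None:
    if fit is None:
        return None
    return {
        "L_p_nm": fit.L_p,
        "ci_low_nm": fit.ci_low,
        "ci_high_nm": None if np.isinf(fit.ci_high) else fit.ci_high,
        "fit_slope_per_nm": fit.fit_slope,
        "fit_intercept": fit.fit_intercept,
        "slope_stderr": fit.slope_stderr,
        "slope_ci": list(fit.slope_ci),
        "youngs_modulus_Pa": fit.E,
        "n_bins_used": fit.n_bins_used,
        "excluded_bins": fit.excluded_bins,
        "constants": fit.constants,
    }


def _ks_to_dict(ks: KSResult | None) -> dict | None:
    if ks is None:
        return None
    return {
        "D": ks.statistic, "p": ks.pvalue, "cutoff_nm": ks.cutoff,
        "n_experimental": ks.n_a, "n_simulated": ks.n_b,
    }


def _band_frame(b: BandSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_left_nm": b.bin_edges[:-1],
            "bin_right_nm": b.bin_edges[1:],
            "median": b.median,
            "p05": b.lower,
            "p95": b.upper,
        }
    )


def write_outputs(
    out_dir: Path,
    config: RunConfig,
    seed: int,
    summaries: dict[str, ConditionSummary],
    anova: AnovaResult | None,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    log_path = out_dir / "log.jsonl"
    events = [
        {"event": "run", "config_hash": cfg_hash, "rng_seed": seed,
         "config": config.to_dict(),
         "multiple_testing_correction": "none"},
    ]

    density_rows, length_rows = [], []
    summary_json: dict = {"config_hash": cfg_hash, "rng_seed": seed, "conditions": {}}
    for name, s in summaries.items():
        for d in s.densities:
            density_rows.append(
                (name, d.tomogram_id, d.cytosolic_volume, d.fibril_volume,
                 d.density, d.n_fibrils)
            )
        for r in s.tomogram_reports:
            for L in r.lengths:
                length_rows.append((name, r.tomogram_id, L))
        for label, b in (
            ("fibril_membrane_experimental", s.fibril_membrane_band),
            ("fibril_membrane_null", s.null_band),
            ("inter_membrane", s.inter_membrane_band),
        ):
            if b is not None:
                _band_frame(b).to_csv(
                    out_dir / f"band_{name}_{label}.csv", index=False
                )
        if s.correlation is not None:
            pd.DataFrame(
                {
                    "separation_nm": s.correlation.separations,
                    "mean_cos": s.correlation.mean_cos,
                    "n_pairs": s.correlation.n_pairs,
                }
            ).to_csv(out_dir / f"tangent_correlation_{name}.csv", index=False)
        summary_json["conditions"][name] = {
            "n_tomograms": len(s.tomogram_reports),
            "n_fibrils": int(sum(len(r.lengths) for r in s.tomogram_reports)),
            "mean_length_nm": (
                float(s.pooled_lengths.mean()) if s.pooled_lengths.size else None
            ),
            "densities": {d.tomogram_id: d.density for d in s.densities},
            "persistence": _fit_to_dict(s.persistence),
            "ks_fibril_membrane": _ks_to_dict(s.ks_fibril_membrane),
            "ks_ensemble": (
                None if s.ks_ensemble is None else {
                    "D": s.ks_ensemble.statistic,
                    "p_mc": s.ks_ensemble.pvalue,
                    "cutoff_nm": s.ks_ensemble.cutoff,
                    "n_simulations": s.ks_ensemble.n_simulations,
                }
            ),
            "notes": s.notes,
        }
        events.append({"event": "condition", "condition": name, "notes": s.notes})

    pd.DataFrame(
        density_rows,
        columns=["condition", "tomogram_id", "cytosolic_volume_nm3",
                 "fibril_volume_nm3", "density", "n_fibrils"],
    ).to_csv(out_dir / "densities.csv", index=False)
    pd.DataFrame(
        length_rows, columns=["condition", "tomogram_id", "length_nm"]
    ).to_csv(out_dir / "lengths.csv", index=False)

    if anova is not None:
        summary_json["anova_densities"] = {
            "F": anova.F, "p": anova.pvalue,
            "group_means": anova.group_means,
            "group_sizes": anova.group_sizes,
            "pairwise_welch_p": anova.pairwise_welch,
        }

    (out_dir / "summary.json").write_text(
        json.dumps(summary_json, indent=2, sort_keys=True, default=float) + "\n"
    )
    with open(log_path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev, sort_keys=True, default=float) + "\n")
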