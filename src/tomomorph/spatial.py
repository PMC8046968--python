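"""Nearest-distance fields and the rigid-motion randomization null.

Distances are measured from fibril centreline points to membrane voxel
centres (no radius correction) via a Euclidean distance transform of
the membrane voxel union, interpolated trilinearly at world
coordinates.  Inter-membrane distances use exact nearest-neighbour
queries between membrane point sets of different organelles.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ComputationError, PlacementError, ValidationError
from .scene import Fibril, TomogramScene

DEFAULT_CONTACT_CUTOFF = 20.0


# ---------------------------------------------------------------------------
# distance fields and samples

def membrane_distance_field(scene: TomogramScene) -> np.ndarray:
    """Distance (nm) from every voxel centre to the nearest membrane
    voxel centre; exact Euclidean distance transform on the grid."""
    mask = scene.membrane_mask
    if not mask.any():
        raise ValidationError(
            f"{scene.tomogram_id}: no membrane voxels; distance field undefined"
        )
    return ndimage.distance_transform_edt(~mask) * scene.voxel_size


@dataclass
class DistanceSample:
    """Pooled point-wise nearest distances with per-point provenance."""

    values: np.ndarray  # nm
    source_ids: np.ndarray  # fibril or organelle id per point

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.source_ids = np.asarray(self.source_ids)

    def __len__(self) -> int:
        return len(self.values)


def fibril_membrane_distances(
    fibrils: list[Fibril],
    field_nm: np.ndarray,
    scene: TomogramScene,
) -> DistanceSample:
    """One distance per fibril point: trilinear interpolation of the
    membrane distance field at world coordinates.

    Fibrils should be resampled at spacing <= the voxel size before
    calling.  Points outside the scene bounds raise, naming the fibril.
    """
    if not fibrils:
        return DistanceSample(values=np.empty(0), source_ids=np.empty(0, dtype=object))
    vals, ids = [], []
    for fib in fibrils:
        inside = scene.contains(fib.points)
        if not inside.all():
            raise ValidationError(
                f"fibril {fib.id!r}: {np.count_nonzero(~inside)} point(s) "
                "outside the scene bounds"
            )
        coords = (fib.points / scene.voxel_size).T
        # Voxel centres sit at integer indices; the outer half-voxel rim of
        # the bounds falls beyond the last centre, where we clamp.
        coords = np.clip(coords, 0.0, (np.array(scene.shape) - 1)[:, None])
        d = ndimage.map_coordinates(field_nm, coords, order=1, mode="nearest")
        vals.append(d)
        ids.extend([fib.id] * len(d))
    return DistanceSample(values=np.concatenate(vals), source_ids=np.array(ids))


def inter_membrane_distances(scene: TomogramScene) -> DistanceSample:
    """For every membrane point of organelle ``k``, the nearest distance
    (nm) to membrane points of any other organelle."""
    ids = sorted(scene.membrane_points)
    if len(ids) < 2:
        raise ValidationError(
            f"{scene.tomogram_id}: inter-membrane analysis undefined with "
            f"{len(ids)} organelle(s); need at least 2"
        )
    vals, out_ids = [], []
    for k in ids:
        others = np.concatenate(
            [scene.membrane_points[j] for j in ids if j != k], axis=0
        )
        tree = cKDTree(others)
        d, _ = tree.query(scene.membrane_points[k], k=1)
        vals.append(d)
        out_ids.extend([k] * len(d))
    return DistanceSample(values=np.concatenate(vals), source_ids=np.array(out_ids))


# ---------------------------------------------------------------------------
# profiles, bands

@dataclass
class DistanceProfile:
    """Normalized histogram of nearest distances over fixed bin edges."""

    bin_edges: np.ndarray  # nm
    frequencies: np.ndarray  # sum to 1 (0 if empty)
    sample_count: int
    source: str = "experimental"  # "experimental" | "simulated"
    tomogram_id: str = "tomogram"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")

    @classmethod
    def from_sample(
        cls,
        values: np.ndarray,
        bin_edges: np.ndarray,
        source: str = "experimental",
        tomogram_id: str = "tomogram",
    ) -> "DistanceProfile":
        values = np.asarray(values, dtype=np.float64)
        counts, _ = np.histogram(values, bins=bin_edges)
        total = counts.sum()
        freqs = counts / total if total > 0 else np.zeros(len(bin_edges) - 1)
        return cls(
            bin_edges=np.asarray(bin_edges, dtype=np.float64),
            frequencies=freqs,
            sample_count=int(values.size),
            source=source,
            tomogram_id=tomogram_id,
        )

    def mass_below(self, cutoff: float) -> float:
        """Fraction of in-range mass in bins entirely below ``cutoff``."""
        sel = self.bin_edges[1:] <= cutoff + 1e-9
        return float(self.frequencies[sel].sum())


@dataclass
class BandSummary:
    """Per-bin median and 5-95 percentile envelope across curves."""

    bin_edges: np.ndarray
    median: np.ndarray
    lower: np.ndarray  # 5th percentile
    upper: np.ndarray  # 95th percentile
    n_curves: int


def band(profiles: list[DistanceProfile]) -> BandSummary:
    if not profiles:
        raise ValidationError("need at least one profile")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if p.bin_edges.shape != edges.shape or not np.allclose(p.bin_edges, edges):
            raise ValidationError("profiles have mismatched bin edges")
    stack = np.vstack([p.frequencies for p in profiles])
    return BandSummary(
        bin_edges=edges,
        median=np.median(stack, axis=0),
        lower=np.percentile(stack, 5, axis=0),
        upper=np.percentile(stack, 95, axis=0),
        n_curves=len(profiles),
    )


# ---------------------------------------------------------------------------
# randomization null

def _admissible_translation(
    points: np.ndarray, bounds: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """Uniform translation keeping all points inside the box, or None."""
    lo = bounds[0] - points.min(axis=0)
    hi = bounds[1] - points.max(axis=0)
    if np.any(hi < lo):
        return None
    return rng.uniform(lo, hi)


def _random_rotation(rng: np.random.Generator, mode: str) -> np.ndarray:
    if mode == "full":
        return Rotation.random(random_state=rng).as_matrix()
    if mode == "in_plane":
        ang = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(ang), np.sin(ang)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    raise ValidationError(f"unknown rotation mode {mode!r}")


def randomize_fibrils(
    scene: TomogramScene,
    fibrils: list[Fibril],
    rng: np.random.Generator,
    rotations: str = "full",
    max_retries: int = 1000,
    forbid_lumen: bool = True,
) -> tuple[list[Fibril], np.ndarray]:
    """Independent rigid motions: uniform rotation about each fibril's
    centroid plus a uniform in-bounds translation; placements with any
    point inside an organelle lumen are rejected and redrawn.

    Returns the randomized fibrils and the per-fibril retry counts.
    """
    out: list[Fibril] = []
    retries = np.zeros(len(fibrils), dtype=np.int64)
    has_lumen = forbid_lumen and bool(scene.organelle_ids)
    for i, fib in enumerate(fibrils):
        placed = None
        for attempt in range(max_retries):
            rot = _random_rotation(rng, rotations)
            c = fib.centroid
            pts = (fib.points - c) @ rot.T
            t = _admissible_translation(pts, scene.bounds, rng)
            if t is None:
                # This orientation cannot fit; spherically infeasible fibrils
                # will exhaust retries below.
                continue
            pts = pts + t
            if has_lumen and np.any(scene.labels_at(pts) > 0):
                continue
            placed = Fibril(points=pts, id=fib.id, radius=fib.radius)
            retries[i] = attempt
            break
        if placed is None:
            span = fib.points.max(axis=0) - fib.points.min(axis=0)
            box = scene.bounds[1] - scene.bounds[0]
            lumen_frac = scene.lumen_volume() / float(np.prod(box))
            raise PlacementError(
                f"fibril {fib.id!r}: no admissible placement in {max_retries} "
                f"retries (extent {span.round(1)} nm, box {box.round(1)} nm, "
                f"lumen fraction {lumen_frac:.2f})"
            )
        out.append(placed)
    return out, retries


@dataclass
class NullEnsemble:
    """Randomized-placement distance profiles with seed provenance."""

    profiles: list[DistanceProfile]
    samples: list[np.ndarray]
    rng_seed: int
    retry_stats: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_simulations(self) -> int:
        return len(self.profiles)

    def pooled_sample(self) -> np.ndarray:
        return np.concatenate(self.samples) if self.samples else np.empty(0)


def _stable_id_hash(text: str) -> int:
    return zlib.crc32(text.encode())


def simulation_rng(seed: int, tomogram_id: str, sim_index: int) -> np.random.Generator:
    """Deterministic per-simulation substream."""
    return np.random.default_rng([seed, _stable_id_hash(tomogram_id), sim_index])


def null_ensemble(
    scene: TomogramScene,
    fibrils: list[Fibril],
    field_nm: np.ndarray,
    bin_edges: np.ndarray,
    n_simulations: int = 200,
    seed: int = 0,
    rotations: str = "full",
    max_retries: int = 1000,
) -> NullEnsemble:
    """``n_simulations`` independent rigid-motion randomizations with
    fibril-membrane distances recomputed and binned for each."""
    if n_simulations < 1:
        raise ValidationError("n_simulations must be >= 1")
    profiles, samples = [], []
    all_retries = np.zeros((n_simulations, len(fibrils)), dtype=np.int64)
    for s in range(n_simulations):
        rng = simulation_rng(seed, scene.tomogram_id, s)
        moved, retries = randomize_fibrils(
            scene, fibrils, rng, rotations=rotations, max_retries=max_retries
        )
        all_retries[s] = retries
        sample = fibril_membrane_distances(moved, field_nm, scene)
        samples.append(sample.values)
        profiles.append(
            DistanceProfile.from_sample(
                sample.values, bin_edges, source="simulated",
                tomogram_id=scene.tomogram_id,
            )
        )
    return NullEnsemble(
        profiles=profiles, samples=samples, rng_seed=seed,
        retry_stats=all_retries,
    )


# ---------------------------------------------------------------------------
# KS comparison

@dataclass
class KSResult:
    statistic: float
    pvalue: float
    cutoff: float
    n_a: int
    n_b: int
    n_truncated_a: int
    n_truncated_b: int


def ks_compare(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> KSResult:
    """Two-sample two-tailed Kolmogorov-Smirnov test on the samples
    truncated to ``[0, cutoff]`` nm (asymptotic p-value)."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    ta = a[(a >= 0) & (a <= cutoff)]
    tb = b[(b >= 0) & (b <= cutoff)]
    if ta.size == 0 or tb.size == 0:
        raise ComputationError(
            f"no mass below cutoff {cutoff} nm "
            f"(n_a={ta.size}, n_b={tb.size} after truncation)"
        )
    res = stats.ks_2samp(ta, tb, alternative="two-sided", method="asymp")
    return KSResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        cutoff=cutoff,
        n_a=int(ta.size),
        n_b=int(tb.size),
        n_truncated_a=int(a.size - ta.size),
        n_truncated_b=int(b.size - tb.size),
    )


@dataclass
class EnsembleKSResult:
    """KS D of the experimental sample against the pooled null, with a
    Monte-Carlo p-value from the rank of that D among leave-one-out
    simulation Ds."""

    statistic: float
    pvalue: float
    cutoff: float
    n_experimental: int
    n_simulations: int
    sim_statistics: np.ndarray


def _truncate(values: np.ndarray, cutoff: float) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64)
    return v[(v >= 0) & (v <= cutoff)]


def _ks_d(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def ensemble_ks_test(
    experimental: np.ndarray,
    simulation_samples: list[np.ndarray],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> EnsembleKSResult:
    """Exchangeability-calibrated sub-cutoff KS comparison.

    The asymptotic two-sample p-value assumes independent observations,
    which point-wise distance samples violate (points along one fibril
    are correlated).  Here each member of {experimental, sim_1, ...,
    sim_n} is scored by its KS D against the pool of the *other*
    simulations; under the null the experimental placement is
    exchangeable with the simulations, so the rank of its D is uniform
    and ``p = (1 + #{D_sim >= D_exp}) / (n + 1)`` is exactly calibrated.
    """
    sims = [_truncate(s, cutoff) for s in simulation_samples]
    sims = [s for s in sims if s.size > 0]
    exp = _truncate(experimental, cutoff)
    if exp.size == 0 or len(sims) < 2:
        raise ComputationError(
            f"no mass below cutoff {cutoff} nm in the experimental sample "
            f"or fewer than 2 non-empty simulations"
        )
    # Symmetric leave-one-out over {exp, sim_1, ..., sim_n}: every member is
    # scored against the pool of all other members, so the collection of Ds
    # is exchangeable under the null and the rank p-value is exact.
    members = [exp] + sims
    pool = np.concatenate(members)
    offsets = np.concatenate([[0], np.cumsum([len(m) for m in members])])
    ds = np.empty(len(members))
    for i, m in enumerate(members):
        others = np.concatenate([pool[: offsets[i]], pool[offsets[i + 1]:]])
        ds[i] = _ks_d(m, others)
    d_exp, d_sims = ds[0], ds[1:]
    p = (1.0 + np.count_nonzero(d_sims >= d_exp)) / (len(sims) + 1.0)
    return EnsembleKSResult(
        statistic=d_exp,
        pvalue=float(p),
        cutoff=cutoff,
        n_experimental=int(exp.size),
        n_simulations=len(sims),
        sim_statistics=d_sims,
    )
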