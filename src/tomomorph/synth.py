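"""Synthetic ground-truth scenes: worm-like-chain fibrils, voxelized
organelles, planted membrane attraction, and gold-label fixtures.

The fibril generator is the inverse model of the tangent-correlation
decay: successive tangents are deflected so that the per-step mean
cosine equals ``exp(-step / L_p)`` exactly, which makes the ensemble
correlation at arc separation ``l`` decay as ``exp(-l / L_p)`` by
independence of the step deflections.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .errors import ComputationError, ValidationError
from .scene import (
    DEFAULT_MIN_FIBRIL_LENGTH,
    Fibril,
    TomogramScene,
)
from .spatial import (
    _admissible_translation,
    _random_rotation,
    membrane_distance_field,
)


# ---------------------------------------------------------------------------
# worm-like chain generation

def _langevin(kappa: float) -> float:
    return 1.0 / np.tanh(kappa) - 1.0 / kappa


def vmf_concentration(mean_cos: float) -> float:
    """Concentration kappa of a von Mises-Fisher step distribution whose
    mean cosine (Langevin function of kappa) equals ``mean_cos``."""
    if not 0.0 < mean_cos < 1.0:
        raise ValidationError(f"mean cosine must be in (0, 1), got {mean_cos}")
    if mean_cos > 1.0 - 1e-6:
        # coth(kappa) - 1/kappa -> 1 - 1/kappa; exact to machine precision here
        return 1.0 / (1.0 - mean_cos)
    return float(
        optimize.brentq(lambda k: _langevin(k) - mean_cos, 1e-9, 1e8, xtol=1e-12)
    )


def _sample_step_cosines(
    kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling of the vMF polar cosine (Wood's formula)."""
    u = rng.uniform(size=n)
    if kappa > 350.0:  # exp(-2*kappa) underflows; truncation is negligible
        w = 1.0 + np.log(u) / kappa
    else:
        e = np.exp(-2.0 * kappa)
        w = 1.0 + np.log(u + (1.0 - u) * e) / kappa
    return np.clip(w, -1.0, 1.0)


def _perpendicular_frame(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(t[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return e1, e2


def generate_wlc_fibril(
    L_p: float,
    length: float,
    step: float,
    rng: np.random.Generator,
    fibril_id: str = "wlc",
    radius: float = 5.0,
) -> Fibril:
    """Discrete 3D worm-like chain with persistence length ``L_p`` (nm).

    At each step the tangent is deflected by a polar angle drawn so that
    the expected cosine is ``exp(-step / L_p)``, with uniform azimuth.
    """
    if not step > 0 or not length > 0 or not L_p > 0:
        raise ValidationError("L_p, length and step must all be > 0")
    if step > L_p / 10.0:
        raise ValidationError(
            f"step {step} nm too coarse for L_p {L_p} nm (need step <= L_p/10)"
        )
    if length < 2 * step:
        raise ValidationError(f"length {length} nm must be >= 2*step")
    n_steps = int(round(length / step))
    kappa = vmf_concentration(np.exp(-step / L_p))
    cosines = _sample_step_cosines(kappa, n_steps - 1, rng)
    azimuths = rng.uniform(0.0, 2.0 * np.pi, size=n_steps - 1)

    t = rng.normal(size=3)
    t /= np.linalg.norm(t)
    tangents = np.empty((n_steps, 3))
    tangents[0] = t
    for i in range(n_steps - 1):
        e1, e2 = _perpendicular_frame(t)
        c = cosines[i]
        s = np.sqrt(max(0.0, 1.0 - c * c))
        t = c * t + s * (np.cos(azimuths[i]) * e1 + np.sin(azimuths[i]) * e2)
        t /= np.linalg.norm(t)
        tangents[i + 1] = t
    points = np.vstack([np.zeros(3), np.cumsum(step * tangents, axis=0)])
    return Fibril(points=points, id=fibril_id, radius=radius)


# ---------------------------------------------------------------------------
# scene specification

@dataclass
class OrganelleSpec:
    """One organelle population to voxelize.

    ``shape``: sphere (size = [radius]), ellipsoid (size = 3 semi-axes)
    or tube (size = [radius, length]); sizes in nm.  ``placement`` is
    "uniform" or "clustered"; clustered organelles are planted with a
    membrane gap to an existing organelle at most ``cluster_spacing``.
    """

    shape: str = "sphere"
    size: tuple[float, ...] = (40.0,)
    count: int = 1
    placement: str = "uniform"
    cluster_spacing: float = 10.0


@dataclass
class FibrilSpec:
    count: int = 50
    persistence_length: float = 1000.0  # nm
    mean_length: float = 250.0  # nm, log-normal mean
    length_sigma: float = 0.4  # log-space sd
    min_length: float = DEFAULT_MIN_FIBRIL_LENGTH
    #: optional truncation keeping fibrils re-placeable by the null sampler
    max_length: float | None = None
    step: float = 5.0
    radius: float = 5.0


@dataclass
class InteractionSpec:
    membrane_attraction_strength: float = 0.0  # in [0, 1]
    attraction_range: float = 20.0  # nm


@dataclass
class SceneSpec:
    """Full recipe for a synthetic scene."""

    box: tuple[float, float, float] = (400.0, 400.0, 150.0)  # nm
    voxel_size: float = 2.0  # nm
    lamella_thickness: float | None = None
    organelles: list[OrganelleSpec] = dc_field(default_factory=list)
    fibrils: FibrilSpec = dc_field(default_factory=FibrilSpec)
    interaction: InteractionSpec = dc_field(default_factory=InteractionSpec)
    rng_seed: int = 0
    tomogram_id: str = "synthetic"
    rejection_budget: int = 2000

    def __post_init__(self) -> None:
        if self.interaction.membrane_attraction_strength > 0:
            if not self.interaction.attraction_range > 0:
                raise ValidationError(
                    "attraction_range must be > 0 when attraction is on"
                )
        if not 0.0 <= self.interaction.membrane_attraction_strength <= 1.0:
            raise ValidationError("attraction strength must be in [0, 1]")


# ---------------------------------------------------------------------------
# voxelization helpers

def _grid_coords(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    ax = [np.arange(n) * voxel_size for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def _voxelize(
    coords: np.ndarray, spec: OrganelleSpec, center: np.ndarray,
    axis: np.ndarray | None = None,
) -> np.ndarray:
    rel = coords - center
    if spec.shape == "sphere":
        (r,) = spec.size
        return np.einsum("...i,...i->...", rel, rel) <= r * r
    if spec.shape == "ellipsoid":
        a = np.asarray(spec.size, dtype=float)
        scaled = rel / a
        return np.einsum("...i,...i->...", scaled, scaled) <= 1.0
    if spec.shape == "tube":
        r, length = spec.size
        u = axis if axis is not None else np.array([0.0, 0.0, 1.0])
        proj = np.einsum("...i,i->...", rel, u)
        closest = np.clip(proj, -length / 2.0, length / 2.0)
        perp = rel - closest[..., None] * u
        return np.einsum("...i,...i->...", perp, perp) <= r * r
    raise ValidationError(f"unknown organelle shape {spec.shape!r}")


def _bounding_radius(spec: OrganelleSpec) -> float:
    if spec.shape == "sphere":
        return spec.size[0]
    if spec.shape == "ellipsoid":
        return max(spec.size)
    if spec.shape == "tube":
        r, length = spec.size
        return float(np.hypot(r, length / 2.0))
    raise ValidationError(f"unknown organelle shape {spec.shape!r}")


# ---------------------------------------------------------------------------
# scene generation

def generate_scene(
    spec: SceneSpec, rng: np.random.Generator | None = None
) -> tuple[TomogramScene, list[Fibril], dict]:
    """Voxelize organelles, place worm-like-chain fibrils, and return
    the scene, the fibrils, and a ground-truth record of everything
    that was planted."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(int(round(b / spec.voxel_size)) for b in spec.box)
    if min(shape) < 2:
        raise ValidationError(f"box {spec.box} too small for voxel {spec.voxel_size}")
    labels = np.zeros(shape, dtype=np.int32)
    coords = _grid_coords(shape, spec.voxel_size)
    box = np.array(spec.box, dtype=float)
    lamella = spec.lamella_thickness if spec.lamella_thickness is not None else box[2]

    organelle_truth = []
    next_label = 1
    centers: list[tuple[np.ndarray, float]] = []  # (center, bounding radius)
    for ospec in spec.organelles:
        for _ in range(ospec.count):
            rad = _bounding_radius(ospec)
            placed = False
            for _ in range(spec.rejection_budget):
                axis = None
                if ospec.shape == "tube":
                    axis = rng.normal(size=3)
                    axis /= np.linalg.norm(axis)
                if ospec.placement == "clustered" and centers:
                    ref_c, ref_r = centers[rng.integers(len(centers))]
                    gap = rng.uniform(spec.voxel_size, ospec.cluster_spacing)
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    center = ref_c + direction * (ref_r + rad + gap)
                else:
                    lo = np.array([rad, rad, max(rad, box[2] - lamella + rad)])
                    hi = np.array([box[0] - rad, box[1] - rad, box[2] - rad])
                    if np.any(hi < lo):
                        raise ValidationError(
                            f"organelle radius {rad} nm does not fit the box"
                        )
                    center = rng.uniform(lo, hi)
                if np.any(center < rad) or np.any(center > box - rad):
                    continue
                mask = _voxelize(coords, ospec, center, axis)
                if not mask.any() or np.any(labels[mask] > 0):
                    continue
                # forbid voxel-adjacent labels merging into a shared membrane
                dil = ndimage.binary_dilation(mask)
                if np.any(labels[dil] > 0) and ospec.placement != "clustered":
                    continue
                labels[mask] = next_label
                centers.append((center, rad))
                organelle_truth.append(
                    {
                        "label": next_label,
                        "shape": ospec.shape,
                        "size_nm": list(ospec.size),
                        "center_nm": center.tolist(),
                        "placement": ospec.placement,
                    }
                )
                next_label += 1
                placed = True
                break
            if not placed:
                frac = float(np.count_nonzero(labels) / labels.size)
                raise ComputationError(
                    f"organelle placement budget exhausted at packing "
                    f"fraction {frac:.3f}"
                )
    frac = float(np.count_nonzero(labels) / labels.size)
    if frac >= 0.5:
        raise ValidationError(f"organelle volume fraction {frac:.2f} >= 0.5")

    scene = TomogramScene(
        label_volume=labels,
        voxel_size=spec.voxel_size,
        lamella_thickness=lamella,
        tomogram_id=spec.tomogram_id,
    )

    field = None
    if scene.organelle_ids and spec.interaction.membrane_attraction_strength > 0:
        field = membrane_distance_field(scene)

    fibrils = _place_fibrils(spec, scene, field, rng)

    truth = {
        "spec": {
            "box_nm": list(spec.box),
            "voxel_size_nm": spec.voxel_size,
            "lamella_thickness_nm": float(lamella),
            "rng_seed": spec.rng_seed,
            "fibrils": {
                "count": spec.fibrils.count,
                "persistence_length_nm": spec.fibrils.persistence_length,
                "mean_length_nm": spec.fibrils.mean_length,
                "length_sigma": spec.fibrils.length_sigma,
                "min_length_nm": spec.fibrils.min_length,
                "step_nm": spec.fibrils.step,
                "radius_nm": spec.fibrils.radius,
            },
            "interaction": {
                "membrane_attraction_strength":
                    spec.interaction.membrane_attraction_strength,
                "attraction_range_nm": spec.interaction.attraction_range,
            },
        },
        "organelles": organelle_truth,
        "fibril_lengths_nm": [f.length for f in fibrils],
        "organelle_volume_fraction": frac,
    }
    return scene, fibrils, truth


def _sample_length(fspec: FibrilSpec, box: np.ndarray, rng) -> float:
    mu = np.log(fspec.mean_length) - fspec.length_sigma**2 / 2.0
    cap = fspec.max_length if fspec.max_length is not None else 10.0 * fspec.mean_length
    # a fibril longer than ~0.9x the largest box edge has no admissible
    # placement for most shapes; cap so the placement loop can terminate
    cap = min(cap, 0.9 * float(np.max(box)))
    if cap <= fspec.min_length:
        raise ValidationError(
            f"box {box} too small for minimum fibril length {fspec.min_length} nm"
        )
    for _ in range(10000):
        val = float(rng.lognormal(mu, fspec.length_sigma))
        if fspec.min_length <= val <= cap:
            return val
    raise ComputationError("could not sample a fibril length in range")


def _place_fibrils(
    spec: SceneSpec,
    scene: TomogramScene,
    field: np.ndarray | None,
    rng: np.random.Generator,
) -> list[Fibril]:
    from .spatial import fibril_membrane_distances  # local: avoid cycle at import

    fspec = spec.fibrils
    strength = spec.interaction.membrane_attraction_strength
    attraction_range = spec.interaction.attraction_range
    box = np.array(spec.box)
    out: list[Fibril] = []
    for i in range(fspec.count):
        placed = None
        # length sampled once per fibril: retrying only shape and placement
        # keeps the realized length distribution free of selection bias
        # against long fibrils in thin slabs
        length = _sample_length(fspec, box, rng)
        for _ in range(spec.rejection_budget):
            fib = generate_wlc_fibril(
                fspec.persistence_length, length, fspec.step, rng,
                fibril_id=f"fib_{i}", radius=fspec.radius,
            )
            rot = _random_rotation(rng, "full")
            pts = (fib.points - fib.centroid) @ rot.T
            t = _admissible_translation(pts, scene.bounds, rng)
            if t is None:
                continue
            pts = pts + t
            if scene.organelle_ids and np.any(scene.labels_at(pts) > 0):
                continue
            candidate = Fibril(points=pts, id=fib.id, radius=fib.radius)
            if field is not None and strength > 0:
                d = fibril_membrane_distances([candidate], field, scene).values
                if d.min() > attraction_range and rng.uniform() < strength:
                    continue
            placed = candidate
            break
        if placed is None:
            raise ComputationError(
                f"fibril placement budget exhausted after {len(out)} fibrils"
            )
        out.append(placed)
    return out


# ---------------------------------------------------------------------------
# gold-label fixture

def generate_gold_fixture(
    k: int,
    spacing: float,
    jitter: float,
    n_labels: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """1D gold-label positions (Å) at every ``k``-th strand of spacing
    ``spacing`` Å, with Gaussian positional jitter."""
    if k < 1 or not spacing > 0:
        raise ValidationError("need k >= 1 and spacing > 0")
    if n_labels < 2:
        raise ValidationError("need at least 2 labels")
    if jitter >= k * spacing / 2.0:
        raise ValidationError(
            f"jitter {jitter} A breaks label ordering (>= k*spacing/2 = "
            f"{k * spacing / 2.0} A)"
        )
    base = np.arange(n_labels, dtype=np.float64) * k * spacing
    if jitter > 0:
        base = base + rng.normal(0.0, jitter, size=n_labels)
    return base
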