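"""Spatial ground-truth scenes and synthetic imaging movies.

A scene places non-overlapping somas in a field of view, grows random-walk
neurites from each soma, and assigns every neurite pixel an expression weight
``exp(-d/lambda_expr)`` where ``d`` is the arclength from the soma edge —
the exponential expression decay of a cytosolic indicator along neurites.
Soma-targeted (ribo-tagged) variants use a several-fold shorter length
constant, confining fluorescence to cell bodies.

Rendering mixes every neuron's soma and neurite footprint with its activity
trace, adds an out-of-focus term (a Gaussian-blurred copy of the full
footprint image, the two-parameter caricature of optical sectioning), an
optional shared neuropil trace, and per-pixel photon noise.  The wide-field
preset uses a much larger out-of-focus weight and blur than the two-photon
preset, reproducing the contamination ordering between the two modalities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from geciquant.transients import Trace

__all__ = [
    "NeuronGeometry",
    "SceneTruth",
    "Movie",
    "OPTICS_PRESETS",
    "DEFAULT_LAMBDA_EXPR_UM",
    "build_scene",
    "render_movie",
    "write_movie",
    "read_movie",
    "write_truth",
    "read_truth",
    "soma_mask_image",
    "neurite_weight_image",
]

#: Default neurite expression length constants (um).  The non-targeted value
#: reflects a cytosolic indicator spreading far into neurites; the
#: soma-targeted value is >5x shorter so that, at the default neurite length,
#: the integrated neurite fluorescence is at most one fifth of the matched
#: non-targeted scene.
DEFAULT_LAMBDA_EXPR_UM = {"non_targeted": 100.0, "soma_targeted": 16.0}

#: Modality presets for the out-of-focus caricature: (background_sigma px,
#: oof_weight).  Wide-field epifluorescence collects far more out-of-focus
#: light than an optically sectioned two-photon system.
OPTICS_PRESETS = {"widefield": (15.0, 1.5), "two_photon": (2.0, 0.05)}


@dataclass(frozen=True)
class NeuronGeometry:
    """Geometry and expression profile of one simulated neuron."""

    centroid: tuple[float, float]  # (x, y) um
    soma_radius: float  # um
    neurites: tuple[np.ndarray, ...]  # polylines, each (k, 2) in um
    targeting: str = "non_targeted"  # {soma_targeted, non_targeted}
    lambda_expr: float = 100.0  # um
    brightness_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.soma_radius <= 0:
            raise ValueError("soma_radius must be > 0")
        if self.lambda_expr <= 0:
            raise ValueError("lambda_expr must be > 0")
        if self.targeting not in ("soma_targeted", "non_targeted"):
            raise ValueError(f"unknown targeting {self.targeting!r}")


@dataclass
class SceneTruth:
    """Ground truth of a simulated field of view."""

    neurons: list[NeuronGeometry]
    fov: tuple[float, float]  # (width, height) um
    pixel_size: float  # um/px
    modality: str = "widefield"
    neuropil_weight: float = 0.0  # mixing weight of the shared neuropil trace
    truth_masks: np.ndarray | None = None  # label image (H, W), 0 = background
    truth_traces: list[Trace] | None = None
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.fov
        return int(round(h / self.pixel_size)), int(round(w / self.pixel_size))

    def centroids_um(self) -> np.ndarray:
        return np.array([n.centroid for n in self.neurons], dtype=float)


@dataclass(frozen=True)
class Movie:
    """A stack of 2-D intensity frames (a.u.)."""

    frames: np.ndarray  # (T, H, W)
    frame_rate: float
    pixel_size: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        object.__setattr__(self, "frames", f)
        if f.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ValueError("frames must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.frames.shape[0])


def _random_walk_neurite(
    rng: np.random.Generator,
    centroid: tuple[float, float],
    soma_radius: float,
    length: float,
    step: float = 2.0,
    angle_sd: float = 0.35,
) -> np.ndarray:
    """Polyline (um) starting at the soma edge, diffusing in direction."""
    theta = rng.uniform(0, 2 * np.pi)
    x = centroid[0] + soma_radius * np.cos(theta)
    y = centroid[1] + soma_radius * np.sin(theta)
    pts = [(x, y)]
    direction = theta
    for _ in range(max(int(np.ceil(length / step)), 1)):
        direction += rng.normal(0.0, angle_sd)
        x += step * np.cos(direction)
        y += step * np.sin(direction)
        pts.append((x, y))
    return np.asarray(pts, dtype=float)


def build_scene(
    n_neurons: int,
    fov: tuple[float, float] = (128.0, 128.0),
    pixel_size: float = 1.0,
    soma_radius_range: tuple[float, float] = (4.0, 6.0),
    neurite_count: int = 4,
    neurite_length: float = 300.0,
    targeting: str = "non_targeted",
    lambda_expr: float | None = None,
    modality: str = "widefield",
    neuropil_weight: float = 0.0,
    brightness_scale: float = 1.0,
    min_gap: float = 0.0,
    seed: int = 0,
    max_tries_per_neuron: int = 2000,
) -> SceneTruth:
    """Place non-overlapping somas, grow neurites and rasterise truth masks.

    Somas are sampled uniformly with a minimum centre distance equal to the
    sum of radii plus ``min_gap`` (um); a packing that cannot be completed within
    ``max_tries_per_neuron`` rejection-sampling attempts raises with a hint to
    lower the density. ``lambda_expr`` defaults per targeting mode
    (:data:`DEFAULT_LAMBDA_EXPR_UM`). Deterministic for a fixed seed.
    """
    if n_neurons < 0:
        raise ValueError("n_neurons must be >= 0")
    w, h = fov
    if abs(w / pixel_size - round(w / pixel_size)) > 1e-9 or abs(
        h / pixel_size - round(h / pixel_size)
    ) > 1e-9:
        raise ValueError("fov must be an integer number of pixels")
    if lambda_expr is None:
        lambda_expr = DEFAULT_LAMBDA_EXPR_UM[targeting]
    rng = np.random.default_rng(seed)

    neurons: list[NeuronGeometry] = []
    centers: list[tuple[float, float, float]] = []  # x, y, r
    for _ in range(n_neurons):
        r = rng.uniform(*soma_radius_range)
        for _try in range(max_tries_per_neuron):
            x = rng.uniform(r, w - r)
            y = rng.uniform(r, h - r)
            if all((x - cx) ** 2 + (y - cy) ** 2 >= (r + cr + min_gap) ** 2 for cx, cy, cr in centers):
                break
        else:
            raise RuntimeError(
                f"could not place {n_neurons} somas in a {w}x{h} um field; "
                "lower the density or soma radius"
            )
        centers.append((x, y, r))
        neurites = tuple(
            _random_walk_neurite(rng, (x, y), r, neurite_length)
            for _ in range(neurite_count)
        )
        neurons.append(
            NeuronGeometry(
                centroid=(x, y),
                soma_radius=r,
                neurites=neurites,
                targeting=targeting,
                lambda_expr=lambda_expr,
                brightness_scale=brightness_scale,
            )
        )

    scene = SceneTruth(
        neurons=neurons,
        fov=fov,
        pixel_size=pixel_size,
        modality=modality,
        neuropil_weight=neuropil_weight,
        seed=seed,
    )
    scene.truth_masks = _label_image(scene)
    return scene


def soma_mask_image(neuron: NeuronGeometry, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean soma mask: pixels whose centre lies within the soma radius."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    # pixel centre (col + 0.5, row + 0.5) in px; positions converted via pixel_size
    px = (cols + 0.5) * pixel_size
    py = (rows + 0.5) * pixel_size
    cx, cy = neuron.centroid
    return (px - cx) ** 2 + (py - cy) ** 2 <= neuron.soma_radius**2


def neurite_weight_image(
    neuron: NeuronGeometry, shape: tuple[int, int], pixel_size: float
) -> np.ndarray:
    """Per-pixel expression weight exp(-d/lambda) along the neuron's neurites.

    ``d`` is the arclength from the soma edge; each pixel takes the maximum
    weight over all passages, so the weight at one length constant from the
    soma edge is e^-1 ~ 36.8% of the soma-edge weight. Pixels inside the soma
    are excluded (they carry the soma signal itself).
    """
    out = np.zeros(shape, dtype=np.float32)
    substep = 0.5 * pixel_size
    for poly in neuron.neurites:
        d = 0.0
        for (x0, y0), (x1, y1) in zip(poly[:-1], poly[1:]):
            seg = float(np.hypot(x1 - x0, y1 - y0))
            if seg == 0:
                continue
            n_sub = max(int(np.ceil(seg / substep)), 1)
            frac = (np.arange(n_sub) + 0.5) / n_sub
            xs = x0 + frac * (x1 - x0)
            ys = y0 + frac * (y1 - y0)
            ds = d + frac * seg
            c = np.floor(xs / pixel_size).astype(int)
            r = np.floor(ys / pixel_size).astype(int)
            ok = (r >= 0) & (r < shape[0]) & (c >= 0) & (c < shape[1])
            wts = np.exp(-ds[ok] / neuron.lambda_expr).astype(np.float32)
            np.maximum.at(out, (r[ok], c[ok]), wts)
            d += seg
    soma = soma_mask_image(neuron, shape, pixel_size)
    out[soma] = 0.0
    return out


def _label_image(scene: SceneTruth) -> np.ndarray:
    labels = np.zeros(scene.shape, dtype=np.int32)
    for i, neuron in enumerate(scene.neurons, start=1):
        labels[soma_mask_image(neuron, scene.shape, scene.pixel_size)] = i
    return labels


def neuron_footprints(
    scene: SceneTruth, neurite_gain: float = 1.0
) -> np.ndarray:
    """Static per-neuron intensity maps, shape (N, H, W): soma + neurites."""
    shape = scene.shape
    maps = np.zeros((len(scene.neurons), *shape), dtype=np.float32)
    for i, neuron in enumerate(scene.neurons):
        soma = soma_mask_image(neuron, shape, scene.pixel_size).astype(np.float32)
        neur = neurite_weight_image(neuron, shape, scene.pixel_size)
        maps[i] = neuron.brightness_scale * (soma + neurite_gain * neur)
    return maps


def render_movie(
    scene: SceneTruth,
    traces: list[Trace],
    shared_neuropil_trace: Trace | None = None,
    background_sigma: float | None = None,
    oof_weight: float | None = None,
    neurite_gain: float = 1.0,
    background_offset: float = 0.1,
    photons_per_unit: float = 200.0,
    read_noise_sd: float = 0.0,
    seed: int = 0,
) -> Movie:
    """Render a noisy movie from a scene and per-neuron activity traces.

    Each frame is the sum of (a) every neuron's soma mask and neurite weight
    map scaled by its trace, (b) ``oof_weight`` times a Gaussian blur (sigma =
    ``background_sigma`` px) of the same image — the out-of-focus/scatter
    term, (c) ``scene.neuropil_weight`` times the shared neuropil trace on
    non-soma pixels, and (d) a constant background offset; photon shot noise
    and read noise are then applied per pixel. Optics parameters default to
    the scene's modality preset. Deterministic given (scene, traces, seed).
    """
    n = len(scene.neurons)
    if len(traces) != n:
        raise ValueError(f"need one trace per neuron ({n}), got {len(traces)}")
    lengths = {len(tr) for tr in traces}
    rates = {tr.frame_rate for tr in traces}
    if len(lengths) > 1 or len(rates) > 1:
        raise ValueError("all traces must share length and frame rate")
    preset_sigma, preset_oof = OPTICS_PRESETS[scene.modality]
    sigma = preset_sigma if background_sigma is None else background_sigma
    oof = preset_oof if oof_weight is None else oof_weight
    n_frames = lengths.pop() if lengths else 0
    frame_rate = rates.pop() if rates else 1.0
    shape = scene.shape

    footprints = neuron_footprints(scene, neurite_gain=neurite_gain)
    if oof > 0:
        blurred = np.stack([gaussian_filter(fp, sigma) for fp in footprints]) if n else footprints
        maps = footprints + np.float32(oof) * blurred
    else:
        maps = footprints

    tmat = np.stack([tr.values for tr in traces]) if n else np.zeros((0, n_frames))
    clean = np.tensordot(tmat.T, maps.reshape(n, -1), axes=1) if n else np.zeros(
        (n_frames, shape[0] * shape[1])
    )
    clean = clean.reshape(n_frames, *shape) + background_offset

    if shared_neuropil_trace is not None and scene.neuropil_weight > 0:
        if len(shared_neuropil_trace) != n_frames:
            raise ValueError("shared neuropil trace length mismatch")
        npil_map = (scene.truth_masks == 0).astype(np.float32)
        clean = clean + (
            scene.neuropil_weight
            * shared_neuropil_trace.values[:, None, None]
            * npil_map[None, :, :]
        )

    from geciquant.transients import add_photon_noise

    flat = Trace(values=clean.ravel(), frame_rate=frame_rate)
    noisy = add_photon_noise(flat, photons_per_unit, read_noise_sd, seed=seed)
    frames = noisy.values.reshape(n_frames, *shape)
    frames = np.clip(frames, 0.0, None)
    return Movie(frames=frames, frame_rate=frame_rate, pixel_size=scene.pixel_size)


# ---------------------------------------------------------------------------
# IO: multi-page TIFF movies, label-image TIFF + JSON truth sidecars


def write_movie(path: str | Path, movie: Movie, dtype: str = "float32", scale: float = 1.0) -> None:
    """Write a movie as a multi-page TIFF (float32, or uint16 after scaling)."""
    path = Path(path)
    meta = {"frame_rate": movie.frame_rate, "pixel_size": movie.pixel_size, "scale": scale}
    if dtype == "float32":
        data = (movie.frames * scale).astype(np.float32)
    elif dtype == "uint16":
        data = np.clip(movie.frames * scale, 0, 65535).round().astype(np.uint16)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric="minisblack")


def read_movie(path: str | Path) -> Movie:
    """Read a movie TIFF written by :func:`write_movie`."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as a TIFF movie: {exc}") from exc
    meta = {"frame_rate": 1.0, "pixel_size": 1.0, "scale": 1.0}
    if desc:
        try:
            meta.update(json.loads(desc))
        except json.JSONDecodeError:
            pass
    if data.ndim == 2:
        data = data[None]
    frames = data.astype(np.float64) / meta["scale"]
    return Movie(frames=frames, frame_rate=meta["frame_rate"], pixel_size=meta["pixel_size"])


def write_truth(directory: str | Path, scene: SceneTruth) -> None:
    """Write ground truth: label-image TIFF plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if scene.truth_masks is None:
        scene.truth_masks = _label_image(scene)
    tifffile.imwrite(directory / "truth_masks.tif", scene.truth_masks.astype(np.int32))
    doc = {
        "fov": list(scene.fov),
        "pixel_size": scene.pixel_size,
        "modality": scene.modality,
        "neuropil_weight": scene.neuropil_weight,
        "seed": scene.seed,
        "neurons": [
            {
                "centroid": list(n.centroid),
                "soma_radius": n.soma_radius,
                "targeting": n.targeting,
                "lambda_expr": n.lambda_expr,
                "brightness_scale": n.brightness_scale,
                "neurites": [p.tolist() for p in n.neurites],
            }
            for n in scene.neurons
        ],
    }
    (directory / "truth.json").write_text(json.dumps(doc, indent=1))


def read_truth(directory: str | Path) -> SceneTruth:
    """Read a ground-truth sidecar written by :func:`write_truth`."""
    directory = Path(directory)
    doc = json.loads((directory / "truth.json").read_text())
    try:
        masks = tifffile.imread(directory / "truth_masks.tif").astype(np.int32)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"cannot parse truth label image: {exc}") from exc
    neurons = [
        NeuronGeometry(
            centroid=tuple(n["centroid"]),
            soma_radius=n["soma_radius"],
            neurites=tuple(np.asarray(p, dtype=float) for p in n["neurites"]),
            targeting=n["targeting"],
            lambda_expr=n["lambda_expr"],
            brightness_scale=n["brightness_scale"],
        )
        for n in doc["neurons"]
    ]
    return SceneTruth(
        neurons=neurons,
        fov=tuple(doc["fov"]),
        pixel_size=doc["pixel_size"],
        modality=doc["modality"],
        neuropil_weight=doc["neuropil_weight"],
        truth_masks=masks,
        seed=doc["seed"],
    )
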