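"""Population-level statistics and the in-silico contamination experiment.

Pairwise Pearson correlations between neurons as a function of centroid
distance, distance-binned correlation profiles, responsive-fraction and
per-FOV summaries, and the orchestrating experiment that renders matched
soma-targeted / non-targeted scenes, extracts somatic and annulus-neuropil
traces, applies the 0.7 neuropil subtraction and quantifies how much of the
inter-neuron correlation was contamination.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from geciquant.biophysics import IndicatorParams
from geciquant.transients import (
    Trace,
    generate_poisson_spike_train,
    SpikeTrain,
    calcium_from_spikes,
    fluorescence_from_calcium,
)
from geciquant.scenes import build_scene, render_movie, SceneTruth, Movie
from geciquant.spatial import (
    masks_from_label_image,
    extract_trace,
    neuropil_annulus_trace,
    neuropil_correct,
)
from geciquant.metrics import (
    BaselineSpec,
    estimate_baseline,
    dff,
    peak_dff,
    peak_snr,
    classify_responsive_zscore,
)

__all__ = [
    "PairCorrelation",
    "CorrelationProfile",
    "PopulationReport",
    "DEFAULT_DISTANCE_BINS_UM",
    "default_contamination_config",
    "pairwise_correlation",
    "bin_correlation",
    "fraction_responsive",
    "per_fov_mean",
    "simulate_population_activity",
    "run_contamination_experiment",
    "run_pipeline",
]

#: Distance bins (um) for the correlation-vs-distance profile.
DEFAULT_DISTANCE_BINS_UM = (0.0, 200.0, 400.0, 800.0)


@dataclass(frozen=True)
class PairCorrelation:
    """Pearson correlation of one unordered neuron pair."""

    id_i: int
    id_j: int
    distance: float  # centroid-to-centroid, um
    pcc: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.id_i == self.id_j:
            raise ValueError("a pair needs two distinct ROIs")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass
class CorrelationProfile:
    """Distance-binned mean pairwise correlation with pair counts."""

    bin_edges: tuple[float, ...]
    mean_pcc: list[float]
    n_pairs: list[int]
    n_dropped: int = 0  # pairs beyond the last edge

    def to_dict(self) -> dict:
        return {
            "bin_edges_um": list(self.bin_edges),
            "mean_pcc": self.mean_pcc,
            "n_pairs": self.n_pairs,
            "n_dropped": self.n_dropped,
        }


@dataclass
class PopulationReport:
    """Per-condition summary of a simulated or analysed population."""

    n_rois: int
    n_responsive: int
    metrics: pd.DataFrame | None = None
    correlation_raw: CorrelationProfile | None = None
    correlation_corrected: CorrelationProfile | None = None
    near_pair_mean_raw: float = float("nan")
    near_pair_mean_corrected: float = float("nan")
    config: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def fraction_responsive(self) -> float:
        return self.n_responsive / self.n_rois if self.n_rois else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_rois": self.n_rois,
            "n_responsive": self.n_responsive,
            "fraction_responsive": self.fraction_responsive,
            "near_pair_mean_raw": self.near_pair_mean_raw,
            "near_pair_mean_corrected": self.near_pair_mean_corrected,
            "correlation_raw": None
            if self.correlation_raw is None
            else self.correlation_raw.to_dict(),
            "correlation_corrected": None
            if self.correlation_corrected is None
            else self.correlation_corrected.to_dict(),
            "config": self.config,
            "seed": self.seed,
        }


def pairwise_correlation(
    traces: list[Trace] | list[np.ndarray],
    centroids: np.ndarray,
    ids: list[int] | None = None,
    corrected: bool = False,
) -> list[PairCorrelation]:
    """Pearson correlation for all unordered neuron pairs.

    ``centroids`` are (x, y) positions in um; distance is Euclidean between
    centroids. ROIs with zero trace variance are skipped with a warning.
    """
    vals = [np.asarray(t.values if hasattr(t, "values") else t, dtype=float) for t in traces]
    if len(vals) < 2:
        raise ValueError("need >= 2 traces")
    if len({v.size for v in vals}) != 1:
        raise ValueError("traces must share length")
    centroids = np.asarray(centroids, dtype=float)
    ids = list(range(len(vals))) if ids is None else list(ids)
    keep = []
    for k, v in enumerate(vals):
        if np.std(v) == 0.0:
            warnings.warn(f"ROI {ids[k]} has zero variance; skipped")
        else:
            keep.append(k)
    if len(keep) < 2:
        raise ValueError("fewer than 2 ROIs with nonzero variance")
    mat = np.corrcoef(np.stack([vals[k] for k in keep]))
    out = []
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            i, j = keep[a], keep[b]
            dist = float(np.linalg.norm(centroids[i] - centroids[j]))
            out.append(
                PairCorrelation(
                    id_i=ids[i], id_j=ids[j], distance=dist,
                    pcc=float(mat[a, b]), corrected=corrected,
                )
            )
    return out


def bin_correlation(
    pairs: list[PairCorrelation],
    bin_edges: tuple[float, ...] = DEFAULT_DISTANCE_BINS_UM,
) -> CorrelationProfile:
    """Mean pairwise correlation per half-open distance bin [lo, hi).

    Pairs at or beyond the last edge are dropped (their count is reported).
    """
    if not pairs:
        raise ValueError("no pairs to bin")
    edges = tuple(float(e) for e in bin_edges)
    if any(e1 <= e0 for e0, e1 in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    means, counts = [], []
    dropped = 0
    vals = [[] for _ in range(len(edges) - 1)]
    for p in pairs:
        idx = None
        for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
            if lo <= p.distance < hi:
                idx = k
                break
        if idx is None:
            dropped += 1
        else:
            vals[idx].append(p.pcc)
    for v in vals:
        counts.append(len(v))
        means.append(float(np.mean(v)) if v else float("nan"))
    return CorrelationProfile(bin_edges=edges, mean_pcc=means, n_pairs=counts, n_dropped=dropped)


def fraction_responsive(flags) -> float:
    """Responsive cells over all cells extracted."""
    flags = list(flags)
    if not flags:
        raise ValueError("no cells")
    return sum(bool(f) for f in flags) / len(flags)


def per_fov_mean(total_count: float, n_fov: int) -> float:
    """Total count divided by the number of fields of view."""
    if n_fov < 1:
        raise ValueError("n_fov must be >= 1")
    return total_count / n_fov


# ---------------------------------------------------------------------------
# Synthetic population activity


def default_contamination_config() -> dict:
    """Shipped default configuration of the contamination experiment.

    Wide-field regime at 128 x 128 px (1 um/px), 30 neurons, 600 frames at
    10 Hz.  Activity mixes independent spiking with population events shared
    across most neurons — the synchronous component that neuropil
    contamination broadcasts across the field.
    """
    return {
        "seed": 0,
        "scene": {
            "n_neurons": 30,
            "fov": [128.0, 128.0],
            "pixel_size": 1.0,
            "modality": "widefield",
            "soma_radius_range": [4.0, 6.0],
            "neurite_count": 4,
            "neurite_length": 300.0,
            "neuropil_weight_base": 0.5,
        },
        "activity": {
            "frame_rate": 10.0,
            "duration_s": 60.0,
            "rate_independent_hz": 0.3,
            "rate_shared_hz": 0.04,
            "participation": 0.5,
            "jitter_s": 0.05,
            "ca_rest_nm": 50.0,
            "a_per_ap_nm": 150.0,
            "tau_ca_s": 1.0,
        },
        "indicator": {"name": "FRCaMPi", "kd": 81.0, "hill_n": 3.1, "f_apo": 1.0, "f_sat": 16.3},
        "optics": {
            "oof_weight": None,  # None -> modality preset
            "background_sigma": None,
            "neurite_gain": 1.0,
            "background_offset": 0.1,
        },
        "noise": {"photons_per_unit": 200.0, "read_noise_sd": 0.0},
        "analysis": {
            "neuropil_r": 0.7,
            "annulus_inner_px": 5.0,
            "annulus_outer_px": 15.0,
            "distance_bins_um": list(DEFAULT_DISTANCE_BINS_UM),
            "near_pair_um": 100.0,
            "responsive_z": 2.5,
        },
    }


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def simulate_population_activity(
    n_neurons: int,
    activity: dict,
    params: IndicatorParams,
    seed: int,
) -> tuple[list[Trace], list[SpikeTrain]]:
    """Spike trains and equilibrium fluorescence traces for a population.

    Every neuron fires an independent Poisson train; population events (a
    second Poisson process) recruit each neuron with probability
    ``participation`` and per-neuron timing jitter, producing the partially
    synchronous activity typical of spontaneous cortical recordings.
    Sub-streams are derived deterministically per neuron index.
    """
    dur = float(activity["duration_s"])
    fr = float(activity["frame_rate"])
    rng = np.random.default_rng(seed)
    shared = generate_poisson_spike_train(
        activity["rate_shared_hz"], dur, seed=rng
    ).times
    traces, spikes = [], []
    for i in range(n_neurons):
        sub = np.random.default_rng((seed, i))
        own = generate_poisson_spike_train(
            activity["rate_independent_hz"], dur, seed=sub
        ).times
        take = sub.random(shared.size) < activity["participation"]
        jit = shared[take] + sub.normal(0.0, activity["jitter_s"], size=int(take.sum()))
        times = np.unique(np.concatenate([own, np.clip(jit, 0.0, np.nextafter(dur, 0.0))]))
        train = SpikeTrain(times=times, duration=dur)
        ca = calcium_from_spikes(
            train,
            ca_rest=activity["ca_rest_nm"],
            a_per_ap=activity["a_per_ap_nm"],
            tau_ca=activity["tau_ca_s"],
            frame_rate=fr,
            duration=dur,
        )
        traces.append(fluorescence_from_calcium(ca, params, mode="equilibrium"))
        spikes.append(train)
    return traces, spikes


def _simulate_condition(
    config: dict, targeting: str, seed: int
) -> tuple[SceneTruth, Movie, list[Trace]]:
    sc = config["scene"]
    scene = build_scene(
        n_neurons=sc["n_neurons"],
        fov=tuple(sc["fov"]),
        pixel_size=sc["pixel_size"],
        soma_radius_range=tuple(sc["soma_radius_range"]),
        neurite_count=sc["neurite_count"],
        neurite_length=sc["neurite_length"],
        targeting=targeting,
        modality=sc["modality"],
        seed=seed,  # same geometry seed for both targeting conditions
    )
    ind = config["indicator"]
    params = IndicatorParams(
        name=ind["name"], kd=ind["kd"], hill_n=ind["hill_n"],
        f_apo=ind["f_apo"], f_sat=ind["f_sat"],
    )
    traces, _ = simulate_population_activity(
        sc["n_neurons"], config["activity"], params, seed=seed + 1
    )
    opt, noi = config["optics"], config["noise"]
    # Shared neuropil field: aggregate neurite fluorescence of the (mostly
    # out-of-view) population, mixed into non-soma pixels.  Its weight scales
    # with the integrated neurite expression, so soma-targeting suppresses it
    # by the same factor it suppresses in-view neurite fluorescence.
    from geciquant.scenes import DEFAULT_LAMBDA_EXPR_UM

    lam = scene.neurons[0].lambda_expr if scene.neurons else 1.0
    length = sc["neurite_length"]
    lam_nt = DEFAULT_LAMBDA_EXPR_UM["non_targeted"]
    mass = lam * (1.0 - np.exp(-length / lam))
    mass_nt = lam_nt * (1.0 - np.exp(-length / lam_nt))
    scene.neuropil_weight = sc.get("neuropil_weight_base", 0.0) * mass / mass_nt
    shared = None
    if scene.neuropil_weight > 0:
        shared = Trace(
            values=np.mean(np.stack([t.values for t in traces]), axis=0),
            frame_rate=traces[0].frame_rate,
        )
    movie = render_movie(
        scene,
        traces,
        shared_neuropil_trace=shared,
        background_sigma=opt["background_sigma"],
        oof_weight=opt["oof_weight"],
        neurite_gain=opt["neurite_gain"],
        background_offset=opt["background_offset"],
        photons_per_unit=noi["photons_per_unit"],
        read_noise_sd=noi["read_noise_sd"],
        seed=seed + 2,
    )
    return scene, movie, traces


def _analyse_condition(scene: SceneTruth, movie: Movie, config: dict, seed: int) -> PopulationReport:
    ana = config["analysis"]
    masks = masks_from_label_image(scene.truth_masks)
    raw = [extract_trace(movie, m) for m in masks]
    neu = [
        neuropil_annulus_trace(
            movie, m, inner=ana["annulus_inner_px"], outer=ana["annulus_outer_px"], exclude=masks
        )
        for m in masks
    ]
    corrected = [
        neuropil_correct(f, fn, r=ana["neuropil_r"]) for f, fn in zip(raw, neu)
    ]
    centroids = np.array(
        [m.centroid_um(scene.pixel_size) for m in masks], dtype=float
    )
    ids = [m.label for m in masks]

    def _zscore(tr: Trace) -> np.ndarray:
        v = tr.values
        sd = np.std(v, ddof=1)
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    pairs_raw = pairwise_correlation([_zscore(t) for t in raw], centroids, ids=ids)
    pairs_cor = pairwise_correlation(
        [_zscore(t) for t in corrected], centroids, ids=ids, corrected=True
    )
    bins = tuple(ana["distance_bins_um"])
    near = ana["near_pair_um"]

    def _near_mean(pairs):
        v = [p.pcc for p in pairs if p.distance < near]
        return float(np.mean(v)) if v else float("nan")

    # spontaneous-activity responsiveness: any quiet-frame z above threshold
    spec = BaselineSpec(method="sliding_percentile", window=200, percentile=20)
    n_resp = 0
    metrics_rows = []
    for m, tr in zip(masks, raw):
        f0 = estimate_baseline(tr, spec)
        d = dff(tr, f0)
        snr = peak_snr(tr, slice(0, len(tr)), noise_basis="low_quantile_sd")
        quiet = d.values[d.values <= np.percentile(d.values, 20)]
        sd = float(np.std(quiet, ddof=1)) if quiet.size > 1 else 0.0
        z = float(np.max(d.values) / sd) if sd > 0 else float("inf")
        responsive = z > ana["responsive_z"]
        n_resp += responsive
        metrics_rows.append(
            {
                "roi_id": m.label,
                "peak_dff": peak_dff(d),
                "peak_snr": snr,
                "responsive": bool(responsive),
            }
        )
    return PopulationReport(
        n_rois=len(masks),
        n_responsive=int(n_resp),
        metrics=pd.DataFrame(metrics_rows),
        correlation_raw=bin_correlation(pairs_raw, bins),
        correlation_corrected=bin_correlation(pairs_cor, bins),
        near_pair_mean_raw=_near_mean(pairs_raw),
        near_pair_mean_corrected=_near_mean(pairs_cor),
        config=config,
        seed=seed,
    )


def run_contamination_experiment(
    config: dict | None = None, seed: int | None = None
) -> dict[str, PopulationReport]:
    """Matched soma-targeted vs non-targeted contamination experiment.

    Both conditions share the same soma placement, activity and noise seeds
    and differ only in targeting (neurite expression length constant). Raw
    and 0.7-neuropil-corrected distance-binned correlations are reported for
    each; the difference quantifies how much correlation the neuropil
    contamination induced and how much of it the subtraction removes.
    """
    cfg = _merge(default_contamination_config(), config)
    if seed is not None:
        cfg["seed"] = seed
    if "seed" not in cfg:
        raise KeyError("config must define 'seed'")
    base_seed = int(cfg["seed"])
    out = {}
    for targeting in ("non_targeted", "soma_targeted"):
        scene, movie, _ = _simulate_condition(cfg, targeting, base_seed)
        out[targeting] = _analyse_condition(scene, movie, cfg, base_seed)
    return out


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> PopulationReport:
    """Full simulate -> render -> extract -> metrics -> correlations pipeline.

    ``config`` follows :func:`default_contamination_config` (missing keys take
    the defaults, but ``seed`` is required). When ``out_dir`` is given a JSON
    manifest and a per-ROI metrics CSV are written there. Deterministic for a
    fixed config + seed.
    """
    if "seed" not in config:
        raise KeyError("config must define 'seed'")
    cfg = _merge(default_contamination_config(), config)
    cfg["seed"] = config["seed"]
    seed = int(cfg["seed"])
    targeting = cfg["scene"].get("targeting", "non_targeted")
    scene, movie, _ = _simulate_condition(cfg, targeting, seed)
    report = _analyse_condition(scene, movie, cfg, seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
        report.metrics.to_csv(out_dir / "metrics.csv", index=False)
    return report
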