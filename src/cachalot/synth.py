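"""Seeded synthetic clicks, click trains, bathymetry and whole survey scenes.

Every downstream stage of the pipeline is testable against known ground
truth generated here, without any field recordings:

* a click is a decaying multipulse packet (p0, p1, p2, p3) whose inter-pulse
  interval (IPI) encodes body length; p1 is the dominant pulse,
* trains follow the three ICI regimes (regular 0.5–2 s, buzz 0.02–0.2 s,
  coda 3–20 clicks over 0.2–2 s),
* the bathymetry emulates a narrow island shelf dropping steeply to a
  continental slope, optionally incised by a canyon,
* a survey scene places 1–9-animal aggregations between configurable
  isobaths, writes per-individual recordings and sighting tables, and keeps
  the full truth for recovery tests.

All generators are pure functions of (spec, seed); randomness flows through
one explicitly passed ``numpy`` generator and no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustics import (
    BUZZ_ICI,
    CODA_CLICKS,
    CODA_DURATION,
    REGULAR_ICI,
    AudioSegment,
    ClickEvent,
    ClickTrain,
)
from .spatial import EARTH_RADIUS_M, BathymetryGrid, GeoPoint, depth_at
from . import io as cio

__all__ = [
    "ClickSpec",
    "TrainSpec",
    "SceneTruth",
    "synth_click",
    "synth_train",
    "synth_bathymetry",
    "synth_survey",
    "study_composition",
]

_METRES_PER_DEGREE = EARTH_RADIUS_M * math.pi / 180.0


@dataclass(frozen=True)
class ClickSpec:
    """Parameters of one animal's click.

    ``pulse_amplitudes`` are relative to p1 = 1.0; the default decay
    (0.3, 1.0, 0.45, 0.2) makes p1 dominant, as most of the click energy
    travels once through the spermaceti organ before reverberating.
    ``snr_db`` is the p1 peak amplitude over the ambient-noise RMS;
    ``math.inf`` means noiseless.
    """

    ipi_ms: float
    pulse_amplitudes: tuple[float, ...] = (0.3, 1.0, 0.45, 0.2)
    pulse_band: tuple[float, float] = (2000.0, 8000.0)
    snr_db: float = 20.0
    sample_rate: float = 96_000.0
    pulse_duration_ms: float = 0.5
    vessel_noise_level: float = 0.0

    def __post_init__(self) -> None:
        if self.ipi_ms <= 0:
            raise ValueError("ipi_ms must be positive")
        amps = self.pulse_amplitudes
        if len(amps) < 1 or len(amps) > 4:
            raise ValueError("between 1 and 4 pulse amplitudes are required")
        if len(amps) > 1 and max(amps) != amps[1]:
            raise ValueError("p1 must be the largest pulse amplitude")
        if self.sample_rate < 2.0 * self.pulse_band[1]:
            raise ValueError(
                f"sample rate {self.sample_rate} Hz is below twice the upper "
                f"passband edge {self.pulse_band[1]} Hz"
            )

    @property
    def n_pulses(self) -> int:
        return sum(1 for a in self.pulse_amplitudes if a > 0)


@dataclass(frozen=True)
class TrainSpec:
    """Parameters of one click train.

    ``ici_s`` is either a constant or a ``(low, high)`` uniform range.  The
    regime invariants are enforced: regular ICIs inside [0.5, 2] s, buzz
    inside [0.02, 0.2] s, codas with 3–20 clicks over 0.2–2 s.
    """

    kind: str
    n_clicks: int
    ici_s: float | tuple[float, float] | None = None
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("regular", "buzz", "coda"):
            raise ValueError(f"unknown train kind {self.kind!r}")
        if self.n_clicks < 1:
            raise ValueError("n_clicks must be >= 1")
        lo, hi = self.ici_range if self.ici_s is not None else (None, None)
        if self.kind == "regular":
            if lo is None or lo < REGULAR_ICI[0] or hi > REGULAR_ICI[1]:
                raise ValueError("regular trains need ICIs inside [0.5, 2] s")
        elif self.kind == "buzz":
            if lo is None or lo < BUZZ_ICI[0] or hi > BUZZ_ICI[1]:
                raise ValueError("buzz trains need ICIs inside [0.02, 0.2] s")
        else:  # coda
            if not CODA_CLICKS[0] <= self.n_clicks <= CODA_CLICKS[1]:
                raise ValueError("codas have 3 to 20 clicks")
            if self.duration_s is None or not (
                CODA_DURATION[0] <= self.duration_s <= CODA_DURATION[1]
            ):
                raise ValueError("codas last 0.2 to 2 s")

    @property
    def ici_range(self) -> tuple[float, float]:
        if self.ici_s is None:
            raise ValueError("ici_s not set")
        if isinstance(self.ici_s, (int, float)):
            return float(self.ici_s), float(self.ici_s)
        return float(self.ici_s[0]), float(self.ici_s[1])


@dataclass
class SceneTruth:
    """Ground truth of a generated survey scene.

    ``individuals`` has one row per animal (id, aggregation, true IPI/length/
    class, position, date, wav path); ``aggregations`` one row per group
    (size, behaviours, truth habitat).  ``audio`` maps individual id to the
    in-memory recording; manifests list any files written.
    """

    individuals: pd.DataFrame
    aggregations: pd.DataFrame
    audio: dict[str, AudioSegment] = field(default_factory=dict)
    audio_manifest: list[str] = field(default_factory=list)
    table_manifest: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# clicks and trains
# ---------------------------------------------------------------------------

def _pulse(spec: ClickSpec, n: int, centre_idx: float, amplitude: float) -> np.ndarray:
    """A Gaussian-windowed tone burst centred at ``centre_idx`` samples."""
    fs = spec.sample_rate
    carrier_hz = 0.5 * (spec.pulse_band[0] + spec.pulse_band[1])
    sigma = spec.pulse_duration_ms * 1e-3 * fs / 4.0
    half = int(round(4 * sigma))
    c = int(round(centre_idx))
    i = np.arange(max(0, c - half), min(n, c + half + 1))
    t = (i - centre_idx) / fs
    window = np.exp(-((i - centre_idx) ** 2) / (2.0 * sigma**2))
    out = np.zeros(n)
    out[i] = amplitude * window * np.cos(2.0 * np.pi * carrier_hz * t)
    return out


def _click_times_samples(spec: ClickSpec, t_click_s: float) -> list[tuple[float, float]]:
    """(centre sample index, amplitude) of each pulse; p1 sits at the click time."""
    fs = spec.sample_rate
    ipi_samp = spec.ipi_ms * 1e-3 * fs
    out = []
    for k, amp in enumerate(spec.pulse_amplitudes):
        if amp > 0:
            out.append((t_click_s * fs + (k - 1) * ipi_samp, amp))
    return out


def _render(
    spec: ClickSpec,
    click_times_s: list[float],
    duration_s: float,
    rng: np.random.Generator,
) -> AudioSegment:
    fs = spec.sample_rate
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    for t_click in click_times_s:
        for centre, amp in _click_times_samples(spec, t_click):
            x += _pulse(spec, n, centre, amp)
    if math.isfinite(spec.snr_db):
        p1_peak = max(spec.pulse_amplitudes)
        sigma = p1_peak / 10.0 ** (spec.snr_db / 20.0)
        x = x + rng.normal(0.0, sigma, n)
    if spec.vessel_noise_level > 0:
        # low-frequency (< 1 kHz) component exercising the high-pass stage
        from scipy.signal import butter, sosfilt

        sos = butter(4, 800.0, btype="lowpass", fs=fs, output="sos")
        x = x + spec.vessel_noise_level * sosfilt(sos, rng.normal(0.0, 1.0, n))
    return AudioSegment(x, fs)


def synth_click(spec: ClickSpec, t0: float, seed: int) -> AudioSegment:
    """Render a single multipulse click whose first pulse sits at ``t0``.

    Pulses fall at ``t0 + k·IPI`` with the specified amplitude decay (the
    dominant p1 one IPI after p0 when p0 is present), embedded in Gaussian
    noise at ``spec.snr_db``.  Bit-identical for a fixed seed.
    """
    if t0 < 0:
        raise ValueError("t0 must be non-negative")
    ipi_s = spec.ipi_ms * 1e-3
    t_p1 = t0 + (ipi_s if spec.pulse_amplitudes[0] > 0 else 0.0)
    tail = len(spec.pulse_amplitudes) * ipi_s + 5e-3
    rng = np.random.default_rng(seed)
    return _render(spec, [t_p1], t_p1 + tail, rng)


def synth_train(
    train: TrainSpec,
    click: ClickSpec,
    seed: int,
    t0: float = 0.1,
) -> tuple[AudioSegment, ClickTrain]:
    """Render a click train and return it with its exact truth.

    Emitted click times (p1 centres, quantized to the sample grid) match the
    returned :class:`~cachalot.acoustics.ClickTrain` exactly; ICIs are drawn
    from the spec's distribution, and for codas the series is rescaled to the
    requested duration.  The truth label equals ``train.kind``.
    """
    rng = np.random.default_rng(seed)
    fs = click.sample_rate
    if train.kind == "coda":
        if train.ici_s is None:
            raw = rng.uniform(0.5, 1.5, train.n_clicks - 1)
        else:
            lo, hi = train.ici_range
            raw = rng.uniform(lo, hi, train.n_clicks - 1) if hi > lo else np.full(train.n_clicks - 1, lo)
        icis = raw / raw.sum() * train.duration_s if train.n_clicks > 1 else np.array([])
    else:
        lo, hi = train.ici_range
        icis = rng.uniform(lo, hi, train.n_clicks - 1) if hi > lo else np.full(train.n_clicks - 1, lo)
    lead = t0 + (click.ipi_ms * 1e-3 if click.pulse_amplitudes[0] > 0 else 0.0)
    times = lead + np.concatenate([[0.0], np.cumsum(icis)])
    times = np.round(times * fs) / fs  # snap to the sample grid: truth is exact
    duration = times[-1] + len(click.pulse_amplitudes) * click.ipi_ms * 1e-3 + 0.1
    audio = _render(click, list(times), duration, rng)
    snr = click.snr_db if math.isfinite(click.snr_db) else 999.0
    truth = ClickTrain(
        clicks=[ClickEvent(time_s=float(t), peak_amplitude=1.0, snr_db=snr) for t in times],
        kind=train.kind,
    )
    return audio, truth


# ---------------------------------------------------------------------------
# bathymetry
# ---------------------------------------------------------------------------

DEFAULT_PROFILE = {
    "shelf_width_m": 2_000.0,
    "shelf_depth_m": 100.0,
    "slope_width_m": 15_000.0,
    "max_depth_m": 2_500.0,
    "canyon": None,
}


def synth_bathymetry(
    n_rows: int,
    n_cols: int,
    cell_m: float,
    profile: dict | None = None,
    seed: int = 0,
    lat0: float = 14.80,
    lon0: float = -61.40,
) -> tuple[BathymetryGrid, list[GeoPoint]]:
    """Generate a shelf–slope bathymetry with the coast along the east edge.

    Depth is a piecewise-linear function of offshore (westward) distance —
    a narrow shelf dropping to ``max_depth_m`` over ``slope_width_m`` — so it
    increases monotonically offshore.  ``profile["canyon"]`` may add a
    Gaussian-shaped incision ``{"amplitude_m", "row_frac", "width_cells"}``.
    Returns the grid and the zero-depth coastline polyline.  Deterministic
    for a fixed seed.
    """
    if n_rows < 2 or n_cols < 2 or cell_m <= 0:
        raise ValueError("grid dimensions and cell size must be positive")
    prof = {**DEFAULT_PROFILE, **(profile or {})}
    if prof["max_depth_m"] <= 0:
        raise ValueError("max_depth_m must be positive")

    dlat = cell_m / _METRES_PER_DEGREE
    cell_ew_m = cell_m * math.cos(math.radians(lat0))
    offshore_m = (n_cols - 1 - np.arange(n_cols)) * cell_ew_m

    shelf_w, shelf_d = prof["shelf_width_m"], prof["shelf_depth_m"]
    slope_w, max_d = prof["slope_width_m"], prof["max_depth_m"]
    depth_col = np.where(
        offshore_m <= shelf_w,
        offshore_m / max(shelf_w, 1e-9) * shelf_d,
        np.minimum(shelf_d + (offshore_m - shelf_w) / max(slope_w, 1e-9) * (max_d - shelf_d), max_d),
    )
    depths = np.tile(depth_col, (n_rows, 1))

    canyon = prof.get("canyon")
    if canyon:
        rows = np.arange(n_rows)
        centre = canyon.get("row_frac", 0.5) * (n_rows - 1)
        width = canyon.get("width_cells", max(2, n_rows // 10))
        shape = np.exp(-((rows - centre) ** 2) / (2.0 * width**2))
        ramp = np.clip(offshore_m / max(shelf_w + slope_w, 1e-9), 0.0, 1.0)
        depths = depths + canyon.get("amplitude_m", 300.0) * shape[:, None] * ramp[None, :]

    roughness = prof.get("roughness_m", 0.0)
    if roughness:
        rng = np.random.default_rng(seed)
        bumps = rng.normal(0.0, roughness, depths.shape)
        depths = np.clip(depths + bumps, 0.0, None)

    grid = BathymetryGrid(depths=depths, lat0=lat0, lon0=lon0, dlat=dlat, dlon=dlat)
    coast_lon = lon0 + (n_cols - 1) * dlat
    coastline = [GeoPoint(lat0 - r * dlat, coast_lon) for r in range(n_rows)]
    return grid, coastline


# ---------------------------------------------------------------------------
# whole survey scenes
# ---------------------------------------------------------------------------

def study_composition() -> dict:
    """Composition rules matching the study's recovered population.

    19 aggregations totalling 74 acoustically characterised individuals:
    16 immatures, 31 adult females / juvenile males, 27 adult males, group
    sizes 1–9, placed between the 1,000 and 2,000 m isobaths.
    """
    return {
        "class_counts": {
            "immature": 16,
            "female_or_juvenile_male": 31,
            "adult_male": 27,
        },
        "isobath_range_m": (1000.0, 2000.0),
        "max_aggregation_size": 9,
        # IPI sampling ranges per class keep 0.1 ms of margin from the
        # 2.9 / 5.0 ms class boundaries and respect the 2 ms floor
        "ipi_ranges_ms": {
            "immature": (2.0, 2.8),
            "female_or_juvenile_male": (3.0, 4.9),
            "adult_male": (5.1, 7.7),
        },
        # aggregations deeper than this are likelier to be hunting
        "hunting_depth_m": 1500.0,
        "p_hunting": (0.25, 0.75),  # (shallow, deep)
        "p_socialising": 0.3,
        "p_moving": 0.5,
        "p_resting": 0.25,
        # adjacent class ranges sit 0.2 ms apart, so 0.25 ms is the largest
        # all-pairs separation that stays feasible; it is comfortably above
        # the 0.15 ms single-linkage tolerance used to count individuals
        "min_ipi_separation_ms": 0.25,
        "min_aggregation_spacing_m": 2000.0,
        "member_scatter_m": 300.0,
        "n_survey_days": 8,
    }


def _partition_sizes(total: int, parts: int, cap: int, rng: np.random.Generator) -> list[int]:
    if not parts * 1 <= total <= parts * cap:
        raise ValueError(f"cannot split {total} individuals into {parts} groups of 1–{cap}")
    sizes = np.ones(parts, dtype=int)
    for _ in range(total - parts):
        open_idx = np.flatnonzero(sizes < cap)
        sizes[rng.choice(open_idx)] += 1
    return sizes.tolist()


def _class_feasible(classes: list[str], ranges: dict, min_sep: float) -> bool:
    counts: dict[str, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    return all(
        (k - 1) * min_sep <= ranges[c][1] - ranges[c][0] for c, k in counts.items()
    )


def _sample_separated_ipis(
    classes: list[str],
    ranges: dict[str, tuple[float, float]],
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 300,
) -> list[float]:
    """IPIs for one group, all pairs >= ``min_sep`` apart.

    Rejection sampling keeps the draws uniform; if the group is crowded the
    fallback spaces each class's animals evenly across its range with a small
    jitter, which guarantees the separation whenever it is feasible at all.
    """
    for _ in range(max_tries):
        ipis = [rng.uniform(*ranges[c]) for c in classes]
        if len(ipis) < 2 or np.min(np.diff(np.sort(ipis))) >= min_sep:
            return ipis
    by_class: dict[str, list[int]] = {}
    for i, c in enumerate(classes):
        by_class.setdefault(c, []).append(i)
    ipis = [0.0] * len(classes)
    for c, idx in by_class.items():
        a, b = ranges[c]
        k = len(idx)
        if k == 1:
            centres = np.array([rng.uniform(a, b)])
            slack = 0.0
        else:
            centres = np.linspace(a, b, k)
            slack = max(min(((b - a) / (k - 1) - min_sep) / 2.0, 0.03), 0.0)
        for i, centre in zip(idx, centres):
            ipis[i] = float(np.clip(centre + rng.uniform(-slack, slack), a, b))
    if len(ipis) > 1 and np.min(np.diff(np.sort(ipis))) < min_sep:
        raise ValueError("group too crowded for acoustically separable IPIs")
    return ipis


def synth_survey(
    n_aggregations: int,
    composition_rules: dict | None = None,
    grid: BathymetryGrid | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_individuals: int | None = None,
    snr_db: float = math.inf,
) -> SceneTruth:
    """Generate a full survey scene with recoverable ground truth.

    Places ``n_aggregations`` groups between the configured isobaths on
    ``grid`` (a default shelf–slope grid is built when omitted), draws each
    animal's class and IPI, renders a per-individual recording (a regular
    click train, plus a buzz when the group hunts and a coda when it
    socialises), and writes WAVs and sighting/truth CSVs under ``out_dir``
    when given.  Default ``snr_db`` is noiseless: recovery tests compare the
    pipeline against the truth without confounding detection noise.
    """
    rules = {**study_composition(), **(composition_rules or {})}
    rng = np.random.default_rng(seed)
    if grid is None:
        grid, _ = synth_bathymetry(120, 100, 250.0, seed=seed)

    empty_ind = pd.DataFrame(
        columns=["individual_id", "aggregation_id", "date", "lat", "lon",
                 "true_ipi_ms", "true_length_m", "class_label", "wav"]
    )
    empty_agg = pd.DataFrame(
        columns=["aggregation_id", "date", "lat", "lon", "size", "behaviours", "depth_m"]
    )
    if n_aggregations == 0:
        return SceneTruth(individuals=empty_ind, aggregations=empty_agg)

    class_counts = dict(rules["class_counts"])
    if n_individuals is None:
        n_individuals = sum(class_counts.values())
        cap = rules["max_aggregation_size"]
        if not n_aggregations <= n_individuals <= n_aggregations * cap:
            # keep the reference population's mean group size (~74/19)
            mean_group = n_individuals / 19.0
            n_individuals = int(np.clip(
                round(n_aggregations * mean_group), n_aggregations, n_aggregations * cap
            ))
    if n_individuals != sum(class_counts.values()):
        # rescale the class mixture to the requested head-count
        probs = np.array(list(class_counts.values()), dtype=float)
        probs /= probs.sum()
        draw = rng.multinomial(n_individuals, probs)
        class_counts = dict(zip(class_counts.keys(), draw.tolist()))

    sizes = _partition_sizes(n_individuals, n_aggregations, rules["max_aggregation_size"], rng)
    labels = [c for c, k in class_counts.items() for _ in range(k)]
    # reshuffle until every group's class composition leaves room for the
    # required IPI separation (with margin, so rejection sampling stays easy)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    for _ in range(100):
        rng.shuffle(labels)
        groups = [labels[bounds[i]:bounds[i + 1]] for i in range(n_aggregations)]
        if all(
            _class_feasible(g, rules["ipi_ranges_ms"], 1.3 * rules["min_ipi_separation_ms"])
            for g in groups
        ):
            break
    else:
        raise ValueError("class mixture too crowded for separable IPIs in some group")

    # candidate cells between the isobaths
    lo_iso, hi_iso = rules["isobath_range_m"]
    rows, cols = np.where((grid.depths >= lo_iso) & (grid.depths <= hi_iso))
    if rows.size < n_aggregations:
        raise ValueError("grid too small: not enough cells between the isobaths")
    # keep half a slope-window of margin from the grid edge
    margin_cells = int(np.ceil(300.0 / (grid.dlat * _METRES_PER_DEGREE))) + 1
    nr, nc = grid.shape
    ok = (
        (rows >= margin_cells) & (rows < nr - margin_cells)
        & (cols >= margin_cells) & (cols < nc - margin_cells)
    )
    rows, cols = rows[ok], cols[ok]
    if rows.size < n_aggregations:
        raise ValueError("grid too small for the requested placements")

    from .spatial import haversine

    spacing = rules["min_aggregation_spacing_m"]
    centres: list[GeoPoint] = []
    for _ in range(8):  # random sequential packing can jam; retry
        centres = []
        order = rng.permutation(rows.size)
        for idx in order:
            cand = GeoPoint(grid.lat0 - rows[idx] * grid.dlat, grid.lon0 + cols[idx] * grid.dlon)
            if all(haversine(cand, c) >= spacing for c in centres):
                centres.append(cand)
            if len(centres) == n_aggregations:
                break
        if len(centres) == n_aggregations:
            break
    if len(centres) < n_aggregations:
        raise ValueError("grid too small to space the requested aggregations")

    # survey dates spanning the two seasonal periods (Jan–Mar and Apr–May)
    days = pd.date_range("2024-01-12", "2024-05-15", periods=rules["n_survey_days"])
    agg_dates = [days[i % len(days)].strftime("%Y-%m-%d") for i in range(n_aggregations)]

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "audio").mkdir(parents=True, exist_ok=True)

    ind_rows, agg_rows = [], []
    audio: dict[str, AudioSegment] = {}
    audio_manifest: list[str] = []
    scatter_deg = rules["member_scatter_m"] / _METRES_PER_DEGREE
    label_cursor = 0
    p_hunt_shallow, p_hunt_deep = rules["p_hunting"]

    for a, (centre, size) in enumerate(zip(centres, sizes)):
        agg_id = f"A{a:02d}"
        members = labels[label_cursor:label_cursor + size]
        label_cursor += size
        ipis = _sample_separated_ipis(
            members, rules["ipi_ranges_ms"], rules["min_ipi_separation_ms"], rng
        )
        depth_truth = depth_at(grid, centre)

        p_hunt = p_hunt_deep if depth_truth >= rules["hunting_depth_m"] else p_hunt_shallow
        behaviours = set()
        if rng.random() < p_hunt:
            behaviours.add("hunting")
        if rng.random() < rules["p_socialising"]:
            behaviours.add("socialising")
        if rng.random() < rules["p_moving"]:
            behaviours.add("moving")
        if rng.random() < rules["p_resting"]:
            behaviours.add("resting")
        if not behaviours:
            behaviours.add("moving")

        for m, (cls, ipi) in enumerate(zip(members, ipis)):
            ind_id = f"{agg_id}I{m}"
            pos = GeoPoint(
                centre.lat + rng.uniform(-scatter_deg, scatter_deg),
                centre.lon + rng.uniform(-scatter_deg, scatter_deg),
            )
            click = ClickSpec(ipi_ms=float(ipi), snr_db=snr_db)
            seg_seed = int(rng.integers(0, 2**31 - 1))
            reg = TrainSpec("regular", n_clicks=10, ici_s=(0.5, 0.9))
            seg, _ = synth_train(reg, click, seed=seg_seed)
            parts = [seg.samples]
            fs = seg.sample_rate
            if "hunting" in behaviours and m == 0:
                buzz, _ = synth_train(
                    TrainSpec("buzz", n_clicks=30, ici_s=0.05), click, seed=seg_seed + 1
                )
                parts += [np.zeros(int(3.0 * fs)), buzz.samples]
            if "socialising" in behaviours and m == min(1, size - 1):
                coda, _ = synth_train(
                    TrainSpec("coda", n_clicks=8, duration_s=1.0), click, seed=seg_seed + 2
                )
                parts += [np.zeros(int(3.0 * fs)), coda.samples]
            full = AudioSegment(np.concatenate(parts), fs)
            audio[ind_id] = full
            wav_path = ""
            if out_dir is not None:
                wav_path = str(out_dir / "audio" / f"{ind_id}.wav")
                cio.write_wav(wav_path, full)
                audio_manifest.append(wav_path)

            from .sizing import size_from_ipi

            ind_rows.append(
                {
                    "individual_id": ind_id,
                    "aggregation_id": agg_id,
                    "date": agg_dates[a],
                    "lat": pos.lat,
                    "lon": pos.lon,
                    "true_ipi_ms": float(ipi),
                    "true_length_m": size_from_ipi(float(ipi)),
                    "class_label": cls,
                    "wav": wav_path,
                }
            )

        agg_rows.append(
            {
                "aggregation_id": agg_id,
                "date": agg_dates[a],
                "lat": centre.lat,
                "lon": centre.lon,
                "size": size,
                "behaviours": ";".join(sorted(behaviours)),
                "depth_m": depth_truth,
            }
        )

    individuals = pd.DataFrame(ind_rows)
    aggregations = pd.DataFrame(agg_rows)

    table_manifest: list[str] = []
    if out_dir is not None:
        sightings = individuals[["date", "lat", "lon", "individual_id", "wav"]].copy()
        visual = aggregations.set_index("aggregation_id")["behaviours"].map(
            lambda b: ";".join(x for x in b.split(";") if x in ("moving", "resting"))
        )
        sightings["visual_behaviours"] = individuals["aggregation_id"].map(visual)
        sightings["notes"] = ""
        for name, frame in (
            ("sightings.csv", sightings),
            ("truth_individuals.csv", individuals),
            ("truth_aggregations.csv", aggregations),
        ):
            p = out_dir / name
            frame.to_csv(p, index=False)
            table_manifest.append(str(p))

    return SceneTruth(
        individuals=individuals,
        aggregations=aggregations,
        audio=audio,
        audio_manifest=audio_manifest,
        table_manifest=table_manifest,
    )
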