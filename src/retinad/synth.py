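"""Synthetic cohort generator with known ground truth.

Emulates the three measurement modalities of a longitudinal two-genotype
(APP/PS1 vs wild-type) mouse study:

* dark-adapted flash ERG traces — a saturating negative photoreceptor
  component (a-wave), a slower positive gamma-shaped lobe (b-wave) and a
  burst of 60–235 Hz oscillatory potentials riding on its rising phase;
* dim-flash scotopic-threshold-response (STR) sweeps dominated by a
  positive pSTR lobe, recorded 30 times per session and averaged;
* OCT B-scan phantoms — a layered reflectance profile (vitreous, inner
  retina, outer retina, RPE, below-RPE) with smoothly undulating
  boundaries, a localized optic-nerve-head dip and multiplicative
  speckle noise;
* novel-object-recognition exploration-time pairs.

The generator's contract is *closed-loop*: applying this package's own
measurement conventions (:mod:`retinad.erg`) to a noise-free trace
recovers every configured amplitude within 2 % relative error.  The
waveform components overlap, so after composition the generator
rescales them iteratively against the extractor until the measured
amplitudes match the requested ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import erg as erg_mod
from . import tables
from .exceptions import (
    CalibrationError,
    ConfigurationError,
    DegenerateGeometryError,
    InvalidParameterError,
)
from .types import BoundarySet, BScan, ErgTrace, NorTrial

# ---------------------------------------------------------------------------
# ERG


@dataclass
class ErgParams:
    """Ground-truth parameters of one simulated ERG session.

    Amplitudes are magnitudes in μV (the a-wave is emitted as a negative
    deflection); latencies are ms *after* the flash.  ``noise_sd`` is
    additive white Gaussian recording noise per sweep.
    """

    a_amp: float = 150.0
    b_amp: float = 200.0
    pstr_amp: float = 100.0
    op_amps: tuple[float, float, float] = (45.0, 60.0, 45.0)
    op_freq: float = 120.0
    a_latency: float = 15.0
    b_latency: float = 100.0
    op_onset: float = 15.0
    pstr_latency: float = 110.0
    noise_sd: float = 10.0
    sampling_rate: float = 1000.0
    flash_time: float = 50.0
    duration: float = 500.0
    flash_cd_s_m2: float = 30.0  # metadata label only

    def validate(self) -> None:
        amps = (self.a_amp, self.b_amp, self.pstr_amp, *self.op_amps)
        if not all(np.isfinite(a) and a >= 0 for a in amps):
            raise InvalidParameterError("amplitudes must be finite and >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if not (60.0 < self.op_freq < 235.0):
            raise InvalidParameterError(
                "op_freq must lie strictly inside the 60–235 Hz pass band"
            )
        if min(self.a_latency, self.b_latency, self.op_onset, self.pstr_latency) <= 0:
            raise InvalidParameterError("latencies must be positive")
        if self.b_latency <= self.a_latency:
            raise InvalidParameterError("b_latency must exceed a_latency")
        if self.duration <= self.flash_time:
            raise InvalidParameterError("duration must exceed flash_time")
        if self.duration <= self.flash_time + self.b_latency:
            raise InvalidParameterError("record ends before the b-wave peak")


def _gamma_lobe(t_ms: np.ndarray, peak_ms: float, order: int = 4) -> np.ndarray:
    """Unit-peak gamma-shaped lobe, zero for t < 0, peaking at ``peak_ms``."""
    y = np.zeros_like(t_ms)
    pos = t_ms > 0
    x = t_ms[pos] / peak_ms
    y[pos] = x**order * np.exp(order * (1.0 - x))
    return y


def _a_component(
    t_ms: np.ndarray, a_latency: float, plateau_frac: float = 0.85
) -> np.ndarray:
    """Unit negative-polarity photoreceptor component (returned positive).

    A transient dip peaking near ``a_latency`` that partially recovers to
    a sustained plateau (``plateau_frac`` of the trough depth).  The
    sharp trough makes the a-wave a localized extremum, while the
    sustained tail keeps the trace below baseline for the rest of the
    record, so trough-to-peak b-wave amplitudes smaller than the a-wave
    magnitude remain representable.  Normalized to unit maximum.
    """
    y = np.zeros_like(t_ms)
    pos = t_ms > 0
    # cubic exponent: C2-smooth onset, negligible energy above 60 Hz so the
    # OP band-pass is not contaminated by the a-wave edge
    sat = 1.0 - np.exp(-((t_ms[pos] / a_latency) ** 3))
    x = t_ms[pos] / a_latency
    bump = x**4 * np.exp(4.0 * (1.0 - x))
    y[pos] = plateau_frac * sat + (1.0 - plateau_frac) * bump
    return y / y.max() if y.max() > 0 else y


def _op_component(
    t_ms: np.ndarray, op_freq: float, op_onset: float, c: np.ndarray
) -> np.ndarray:
    """Oscillatory potentials: Gaussian-windowed sinusoid wavelets.

    One wavelet per OP, carrier at ``op_freq``, crests two carrier
    periods apart and envelope width ``sigma = period / 3.0``.  The
    narrow envelopes make the three peaks individually resolvable and
    keep their peak-to-preceding-trough amplitudes nearly decoupled, so
    the closed-loop calibration can hit arbitrary (non-extreme)
    amplitude patterns.
    """
    period = 1000.0 / op_freq
    sigma = period / 3.0
    t_peaks = op_onset + period + 2.0 * period * np.arange(c.size)
    y = np.zeros_like(t_ms)
    for ck, tk in zip(c, t_peaks):
        if ck <= 0:
            continue
        y += (
            ck
            * np.exp(-((t_ms - tk) ** 2) / (2.0 * sigma**2))
            * np.cos(2.0 * np.pi * op_freq * (t_ms - tk) / 1000.0)
        )
    return y


def erg_waveform(params: ErgParams, calibrate: bool = True) -> np.ndarray:
    """Noise-free bright-flash waveform honouring the closed-loop contract.

    Composes the three components and, because they overlap, iteratively
    rescales each against the package's own extractor until the measured
    a-, b- and OP amplitudes sit within 1.5 % of the configured values
    (inside the 2 % contract).
    """
    params.validate()
    n = int(round(params.duration * params.sampling_rate / 1000.0))
    t = np.arange(n) * 1000.0 / params.sampling_rate
    tp = t - params.flash_time

    a_unit = _a_component(tp, params.a_latency)
    b_unit = _gamma_lobe(tp, params.b_latency)
    targets_op = np.asarray(params.op_amps, dtype=float)

    s_a = params.a_amp
    s_b = params.b_amp
    c = targets_op / 2.0

    def compose(s_a: float, s_b: float, c: np.ndarray) -> np.ndarray:
        y = -s_a * a_unit + s_b * b_unit
        if np.any(c > 0):
            y = y + _op_component(tp, params.op_freq, params.op_onset, c)
        return y

    if not calibrate or (params.a_amp == 0 and params.b_amp == 0 and not np.any(targets_op)):
        return compose(s_a, s_b, c)

    # Damped multiplicative fixed point.  Converges for physiological
    # amplitude patterns (adjacent OP ratios up to ~2.5); strongly skewed
    # patterns are not resolvable as three distinct wavelets and raise.
    tol = 0.015
    for it in range(120):
        y = compose(s_a, s_b, c)
        trace = ErgTrace(y, params.sampling_rate, params.flash_time)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ab = erg_mod.measure_ab(trace)
            op_m = np.zeros(3)
            if np.any(targets_op > 0):
                filtered = erg_mod.isolate_ops(trace)
                amps, _ = erg_mod.measure_ops(filtered)
                op_m = np.asarray(amps, dtype=float)

        # diminishing step size suppresses limit cycles caused by discrete
        # switches in peak selection
        lam = 1.0 if it < 10 else (0.5 if it < 40 else 0.3)
        errs: list[float] = []
        if params.a_amp > 0:
            a_m = -ab.a_amp
            if a_m <= 0:
                raise CalibrationError("measured a-wave lost its polarity")
            errs.append(abs(a_m - params.a_amp) / params.a_amp)
            s_a *= float(np.clip(params.a_amp / a_m, 0.7, 1.4)) ** lam
        if params.b_amp > 0:
            if ab.b_amp <= 0:
                raise CalibrationError("measured b-wave collapsed to zero")
            errs.append(abs(ab.b_amp - params.b_amp) / params.b_amp)
            s_b *= float(np.clip(params.b_amp / ab.b_amp, 0.7, 1.4)) ** lam
        for k in range(3):
            if targets_op[k] > 0:
                if op_m[k] <= 0:
                    raise CalibrationError(f"OP{k + 1} not resolvable during calibration")
                errs.append(abs(op_m[k] - targets_op[k]) / targets_op[k])
                c[k] *= float(np.clip(targets_op[k] / op_m[k], 0.7, 1.4)) ** lam
        if not errs or max(errs) < tol:
            return compose(s_a, s_b, c)
    raise CalibrationError(
        f"amplitude calibration did not converge (last max error {max(errs):.3%})"
    )


def simulate_erg_trace(params: ErgParams, seed: int | np.random.Generator = 0) -> ErgTrace:
    """One noisy bright-flash ERG sweep."""
    rng = np.random.default_rng(seed)
    clean = erg_waveform(params)
    noisy = clean + rng.normal(0.0, params.noise_sd, size=clean.size)
    return ErgTrace(noisy, params.sampling_rate, params.flash_time, label="bright-flash")


def str_waveform(params: ErgParams) -> np.ndarray:
    """Noise-free dim-flash STR waveform (pSTR lobe only).

    The lobe peaks exactly at ``pstr_amp`` above baseline, so the
    baseline-to-peak convention recovers it without rescaling.
    """
    params.validate()
    n = int(round(params.duration * params.sampling_rate / 1000.0))
    t = np.arange(n) * 1000.0 / params.sampling_rate
    return params.pstr_amp * _gamma_lobe(t - params.flash_time, params.pstr_latency)


def simulate_str_trace(
    params: ErgParams, n_flashes: int = 30, seed: int | np.random.Generator = 0
) -> list[ErgTrace]:
    """``n_flashes`` independent noisy dim-flash sweeps."""
    if n_flashes < 1:
        raise InvalidParameterError("n_flashes must be >= 1")
    rng = np.random.default_rng(seed)
    clean = str_waveform(params)
    return [
        ErgTrace(
            clean + rng.normal(0.0, params.noise_sd, size=clean.size),
            params.sampling_rate,
            params.flash_time,
            label="dim-STR",
        )
        for _ in range(n_flashes)
    ]


# ---------------------------------------------------------------------------
# OCT phantom


@dataclass
class BScanParams:
    """Geometry and reflectance of one phantom B-scan.

    ``boundary_means_um`` are the mean axial depths of the ILM, the
    INL/OPL interface and the RPE base; implied inner thickness is
    ``inl_opl - ilm`` and outer thickness ``rpe_base - inl_opl``.
    ``boundary_smoothness`` is the amplitude (px) of the low-order
    undulation shared by all boundaries; each boundary additionally
    wanders independently by a quarter of it.
    """

    height: int = 96
    width: int = 120
    axial_px_um: float = 3.9
    boundary_means_um: tuple[float, float, float] = (117.0, 148.2, 202.9)
    boundary_smoothness: float = 2.0
    onh_center_col: int | None = None
    onh_width: int = 12
    onh_dip_px: float = 8.0
    # vitreous, inner retina, outer retina, RPE, below-RPE reflectance.
    # Chosen so the vitreous/ILM step is the strongest dark-to-light edge
    # and the RPE base the strongest light-to-dark edge, matching the
    # sequential search order of the segmentation.
    layer_intensities: tuple[float, float, float, float, float] = (
        0.03, 0.60, 0.35, 0.85, 0.06,
    )
    rpe_thickness_um: float = 12.0
    speckle_sd: float = 0.15
    n_bscans: int = 5
    bscan_spacing_um: float = 125.0

    def validate(self) -> None:
        if self.height < 32 or self.width < 32:
            raise InvalidParameterError("phantom must be >= 32x32 px")
        if self.axial_px_um <= 0:
            raise InvalidParameterError("axial_px_um must be positive")
        d = np.diff(self.boundary_means_um)
        if np.any(d <= 0):
            raise InvalidParameterError("boundary depths must be strictly increasing")
        if self.speckle_sd < 0:
            raise InvalidParameterError("speckle_sd must be >= 0")
        if self.boundary_smoothness < 0:
            raise InvalidParameterError("boundary_smoothness must be >= 0")
        if self.rpe_thickness_um <= 0:
            raise InvalidParameterError("rpe_thickness_um must be positive")

    @classmethod
    def from_thickness(
        cls, inner_um: float, outer_um: float, ilm_depth_um: float = 117.0, **kw
    ) -> "BScanParams":
        """Phantom encoding the given inner/outer thickness."""
        return cls(
            boundary_means_um=(
                ilm_depth_um,
                ilm_depth_um + inner_um,
                ilm_depth_um + inner_um + outer_um,
            ),
            **kw,
        )


def _undulation(width: int, amp_px: float, rng: np.random.Generator) -> np.ndarray:
    """Low-order lateral undulation with exactly zero column mean.

    Sum of the first three integer-period Fourier modes with random
    phases; integer periods make the discrete mean vanish exactly, so
    undulation does not bias the mean thickness.
    """
    cols = np.arange(width)
    y = np.zeros(width)
    if amp_px > 0:
        weights = amp_px * np.array([1.0, 0.5, 0.25])
        for m, w in zip((1, 2, 3), weights):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            y += w * np.sin(2.0 * np.pi * m * cols / width + phase)
    return y


def simulate_bscan(
    params: BScanParams, seed: int | np.random.Generator = 0
) -> tuple[BScan, BoundarySet]:
    """One phantom B-scan plus its ground-truth boundaries.

    Bands are rendered with partial-volume (area-weighted) pixels at
    each boundary crossing, then multiplied by ``1 + speckle_sd * N(0,1)``
    (clipped at zero).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    H, W = params.height, params.width
    scale = params.axial_px_um

    base = _undulation(W, params.boundary_smoothness, rng)
    onh_c = params.onh_center_col if params.onh_center_col is not None else W // 2
    sigma = max(params.onh_width / 2.0, 1.0)
    dip = params.onh_dip_px * np.exp(-((np.arange(W) - onh_c) ** 2) / (2.0 * sigma**2))

    curves = []
    for mean_um in params.boundary_means_um:
        wiggle = _undulation(W, params.boundary_smoothness / 4.0, rng)
        curves.append(mean_um / scale + base + wiggle + dip)
    ilm, inl_opl, rpe_base = curves
    rpe_top = rpe_base - params.rpe_thickness_um / scale

    stack = np.vstack([np.zeros(W), ilm, inl_opl, rpe_top, rpe_base, np.full(W, float(H))])
    if np.any(np.diff(stack, axis=0) <= 0) or np.any(rpe_base >= H - 1) or np.any(ilm <= 1):
        raise DegenerateGeometryError(
            "boundary curves cross or leave the image after undulation/dip"
        )

    rows = np.arange(H)[:, None]
    img = np.zeros((H, W))
    for i, inten in enumerate(params.layer_intensities):
        top, bot = stack[i], stack[i + 1]
        cover = np.clip(np.minimum(bot, rows + 1) - np.maximum(top, rows), 0.0, 1.0)
        img += inten * cover
    if params.speckle_sd > 0:
        img = img * (1.0 + params.speckle_sd * rng.standard_normal((H, W)))
        img = np.clip(img, 0.0, None)

    onh_half = max(int(round(0.05 * W)), params.onh_width // 2)
    bscan = BScan(
        image=img,
        axial_px_um=scale,
        onh_cols=(max(0, onh_c - onh_half), min(W, onh_c + onh_half)),
    )
    # Ground truth is reported in pixel-centre coordinates: an interface at
    # band coordinate d (pixel d is the first row of the new band) produces
    # its gradient response centred on d - 0.5.
    truth = BoundarySet(
        ilm=ilm - 0.5, inl_opl=inl_opl - 0.5, rpe_base=rpe_base - 0.5
    )
    return bscan, truth


# ---------------------------------------------------------------------------
# Behaviour


def simulate_nor_trial(
    mean_novel: float,
    mean_familiar: float,
    sd: float,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Noisy (novel, familiar) exploration-time pair, truncated at zero."""
    if mean_novel < 0 or mean_familiar < 0:
        raise InvalidParameterError("mean exploration times must be >= 0")
    if sd < 0:
        raise InvalidParameterError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    novel = max(0.0, mean_novel + rng.normal(0.0, sd))
    familiar = max(0.0, mean_familiar + rng.normal(0.0, sd))
    return novel, familiar


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class CohortDesign:
    """Two-genotype × four-age longitudinal design with per-cell means.

    Defaults reproduce the published cohort: n = 15 animals per group
    per time point, between-animal SDs equal to the printed ± values,
    recording-level noise on top.
    """

    genotypes: tuple[str, ...] = tables.GENOTYPES
    ages: tuple[int, ...] = tables.AGES_MONTHS
    nor_ages: tuple[int, ...] = tables.NOR_AGES_MONTHS
    n_per_cell: int = 15
    erg_means: dict = field(default_factory=lambda: dict(tables.ERG_MEANS))
    thickness_means: dict = field(default_factory=lambda: dict(tables.THICKNESS_MEANS))
    nor_means: dict = field(default_factory=lambda: dict(tables.NOR_MEANS))
    n_str_flashes: int = 30
    erg_noise_sd: float = 10.0
    speckle_sd: float = 0.15
    n_bscans: int = 5
    bscan_spacing_um: float = 125.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_cell < 2:
            raise ConfigurationError("n_per_cell must be >= 2")
        for g in self.genotypes:
            for a in self.ages:
                if (g, a) not in self.erg_means:
                    raise ConfigurationError(f"missing ERG parameter cell ({g}, {a})")
                if (g, a) not in self.thickness_means:
                    raise ConfigurationError(
                        f"missing thickness parameter cell ({g}, {a})"
                    )
            for a in self.nor_ages:
                if (g, a) not in self.nor_means:
                    raise ConfigurationError(f"missing NOR parameter cell ({g}, {a})")


@dataclass
class AnimalRecord:
    """Raw synthetic data of one animal at one age."""

    animal_id: str
    genotype: str
    age_months: int
    truth: dict[str, float]
    erg_bright: ErgTrace | None = None
    str_traces: list[ErgTrace] = field(default_factory=list)
    bscans: list[BScan] = field(default_factory=list)
    bscan_truths: list[BoundarySet] = field(default_factory=list)
    nor: NorTrial | None = None


@dataclass
class CohortData:
    design: CohortDesign
    animals: list[AnimalRecord]

    def cell(self, genotype: str, age: int) -> list[AnimalRecord]:
        return [
            a for a in self.animals if a.genotype == genotype and a.age_months == age
        ]


def _cell_rng(seed: int, g_idx: int, a_idx: int, animal: int, channel: int) -> np.random.Generator:
    # Independent stream per (cell, animal, modality) so that switching a
    # modality on or off leaves the others byte-identical.
    return np.random.default_rng(
        np.random.SeedSequence((seed, g_idx, a_idx, animal, channel))
    )


def draw_animal_truth(
    design: CohortDesign, genotype: str, age: int, rng: np.random.Generator
) -> dict[str, float]:
    """Per-animal ground-truth parameters: cell mean + between-animal deviation."""
    e = design.erg_means[(genotype, age)]
    t = design.thickness_means[(genotype, age)]
    # b-wave and total OP are drawn jointly with rejection: a waveform whose
    # largest OP wavelet rivals the trough-to-peak b-wave is self-contradictory
    # under the measurement conventions (the OP crest would *be* the b-peak),
    # so such tail draws cannot occur in a measured cohort either.
    # Amplitude draws are floored at 20 % of the cell mean: the normal is a
    # modelling convenience for the printed mean ± SD, and its extreme lower
    # tail (amplitudes near zero) would be unmeasurable in a real recording.
    def amp(mean: float, sd: float) -> float:
        return max(0.2 * mean, mean + rng.normal(0.0, sd))

    for _ in range(100):
        b_amp = amp(e["b"], e["b_sd"])
        op_total = amp(e["op"], e["op_sd"])
        if max(OP_SPLIT) * op_total <= 0.7 * b_amp:
            break
    else:
        raise ConfigurationError(
            f"cell ({genotype}, {age}) cannot produce a consistent b/OP pair"
        )
    truth = {
        "a_amp": amp(abs(e["a"]), e["a_sd"]),
        "b_amp": b_amp,
        "pstr_amp": amp(e["pstr"], e["pstr_sd"]),
        "op_total": op_total,
        "inner_um": max(5.0, t["inner"] + rng.normal(0.0, t["inner_sd"])),
        "outer_um": max(5.0, t["outer"] + rng.normal(0.0, t["outer_sd"])),
    }
    if (genotype, age) in design.nor_means:
        n = design.nor_means[(genotype, age)]
        truth["nor_novel"] = n["novel"]
        truth["nor_familiar"] = n["familiar"]
        truth["nor_sd"] = n["sd"]
    return truth


#: Fixed split of the total OP amplitude over OP1–OP3 (middle wavelet
#: dominant, as in dark-adapted rodent recordings).
OP_SPLIT = (0.3, 0.4, 0.3)


def erg_params_for(truth: dict[str, float], design: CohortDesign) -> ErgParams:
    op = truth["op_total"]
    return ErgParams(
        a_amp=truth["a_amp"],
        b_amp=truth["b_amp"],
        pstr_amp=truth["pstr_amp"],
        op_amps=tuple(op * f for f in OP_SPLIT),  # type: ignore[arg-type]
        noise_sd=design.erg_noise_sd,
    )


def simulate_cohort(
    design: CohortDesign | None = None,
    modalities: tuple[str, ...] = ("erg", "oct", "nor"),
) -> CohortData:
    """Full raw dataset: per animal one bright-flash ERG, 30 dim-flash
    STR sweeps, 5 B-scans and (at eligible ages) one NOR trial.

    Deterministic given ``design.seed``; each animal/modality has an
    independent seeded stream.
    """
    design = design or CohortDesign()
    design.validate()
    animals: list[AnimalRecord] = []
    for gi, g in enumerate(design.genotypes):
        for ai, age in enumerate(design.ages):
            for k in range(design.n_per_cell):
                rng_truth = _cell_rng(design.seed, gi, ai, k, 0)
                # Rare tail draws produce waveforms whose tiny OPs drown in
                # the band-pass leakage of the slow components and cannot
                # satisfy the closed-loop contract; the generator emits only
                # measurable waveforms, so such truths are redrawn.
                for _attempt in range(10):
                    truth = draw_animal_truth(design, g, age, rng_truth)
                    rec = AnimalRecord(
                        animal_id=f"{g.replace('/', '')}-{age:02d}m-{k:03d}",
                        genotype=g,
                        age_months=age,
                        truth=truth,
                    )
                    if "erg" not in modalities:
                        break
                    try:
                        p = erg_params_for(truth, design)
                        rec.erg_bright = simulate_erg_trace(
                            p, _cell_rng(design.seed, gi, ai, k, 1)
                        )
                        rec.str_traces = simulate_str_trace(
                            p,
                            design.n_str_flashes,
                            _cell_rng(design.seed, gi, ai, k, 2),
                        )
                        break
                    except CalibrationError:
                        continue
                else:
                    raise CalibrationError(
                        f"animal {rec.animal_id}: no resolvable waveform in 10 draws"
                    )
                if "oct" in modalities:
                    bp = BScanParams.from_thickness(
                        truth["inner_um"],
                        truth["outer_um"],
                        speckle_sd=design.speckle_sd,
                        n_bscans=design.n_bscans,
                        bscan_spacing_um=design.bscan_spacing_um,
                    )
                    rng_oct = _cell_rng(design.seed, gi, ai, k, 3)
                    for s in range(design.n_bscans):
                        scan, btruth = simulate_bscan(bp, rng_oct)
                        scan.scan_id = f"{rec.animal_id}-b{s}"
                        rec.bscans.append(scan)
                        rec.bscan_truths.append(btruth)
                if "nor" in modalities and "nor_novel" in truth:
                    novel, familiar = simulate_nor_trial(
                        truth["nor_novel"],
                        truth["nor_familiar"],
                        truth["nor_sd"],
                        _cell_rng(design.seed, gi, ai, k, 4),
                    )
                    rec.nor = NorTrial(
                        novel=novel,
                        familiar=familiar,
                        animal_id=rec.animal_id,
                        age_months=age,
                    )
                animals.append(rec)
    return CohortData(design=design, animals=animals)
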