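"""Synthetic auditory-evoked EEG with known ground truth.

Emulates the study's recording protocol — 62 cephalic channels referenced to
the right earlobe, 1000 Hz sampling, 1000 ms epochs from −200 to 800 ms,
1 Hz trains of 36 ms biphasic-pulse stimulus artifact — with dipolar sources
in left and right auditory cortex whose morphology is either the mature
P1-N1-P2 complex (established, first-implanted ear) or the immature two-lobe
N(CI)-P(CI) complex that the long-deprived ear evokes.

The longitudinal generator plants the study's qualitative effect structure
with tunable sizes: a left-hemisphere activation bias, a linear dependence of
ear-dominance (cortical representation) on inter-implant delay, amplitude
decay of second-implant and bilateral responses over sessions with stable
first-implant responses, and bilateral enhancement present in the right but
not the left auditory cortex. Ground-truth tables always accompany the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .cohort import TimeBin
from .montage import standard_62_montage
from .source_imaging import HeadModel, build_head_model, leadfield_for_dipoles

__all__ = [
    "SourceSpec",
    "SimulationConfig",
    "EffectModel",
    "epoch_times",
    "make_component_waveform",
    "make_ci_artifact",
    "artifact_topography",
    "simulate_epochs",
    "simulate_longitudinal_cohort",
    "simulate_speech_scores",
    "default_sources",
]

#: Session time-bin mean ± SD of days since activation, as recorded in the study
SESSION_DAYS = {
    TimeBin.WEEKS_1_2: (8.7, 3.3),
    TimeBin.MONTHS_1_2: (42.4, 6.7),
    TimeBin.MONTHS_3_4: (100.5, 9.5),
    TimeBin.MONTHS_6_14: (285.1, 85.5),
}

LEFT_AC = (-60.0, -25.0, 8.0)
RIGHT_AC = (60.0, -25.0, 8.0)


@dataclass
class SourceSpec:
    """A dipolar source: MNI location (mm), unit orientation, waveform (nA·m)."""

    location: tuple
    orientation: tuple
    waveform: np.ndarray
    label: str = "other"

    def __post_init__(self):
        ori = np.asarray(self.orientation, float)
        n = np.linalg.norm(ori)
        if n == 0:
            raise ValueError("orientation must be a nonzero vector")
        self.orientation = tuple(ori / n)
        self.waveform = np.asarray(self.waveform, float)


@dataclass
class SimulationConfig:
    """Recording-protocol parameters; the seed fully determines the output."""

    n_channels: int = 62
    fs: float = 1000.0
    epoch_window: tuple = (-200.0, 800.0)
    n_epochs: int = 200
    noise_sd: float = 15.0            # μV per sample, single trial
    artifact_amplitude: float = 500.0  # μV peak at the implant-side maximum
    artifact_duration: float = 36.0    # ms
    artifact_carrier: float = 250.0    # pulses per second
    morphology: str = "mature_P1N1P2"
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        t0, t1 = self.epoch_window
        if not (t0 <= -200.0 + 1e-9 and t1 >= 400.0):
            raise ValueError("epoch window must span the baseline and response")


def epoch_times(config: SimulationConfig) -> np.ndarray:
    """Sample times in ms, e.g. −200 .. 799 at 1000 Hz."""
    t0, t1 = config.epoch_window
    n = int(round((t1 - t0) * config.fs / 1000.0))
    return t0 + np.arange(n) * 1000.0 / config.fs


MORPHOLOGIES = {
    # label: (latencies ms, relative amplitudes, gaussian sigmas ms)
    "mature_P1N1P2": ((70.0, 95.0, 175.0), (0.3, -1.0, 0.6), (8.0, 14.0, 25.0)),
    "immature_NciPci": ((97.0, 200.0), (-1.0, 0.55), (16.0, 30.0)),
}


def make_component_waveform(times: np.ndarray, morphology: str = None, *,
                            latencies=None, amplitudes=None, widths=None,
                            support_sigmas: float = 4.0) -> np.ndarray:
    """Sum of signed Gaussian lobes with compact support.

    Either pass a named ``morphology`` (latency/amplitude/width defaults for
    the mature three-lobe or immature two-lobe complex) or explicit arrays.
    Each lobe is zeroed outside ``latency ± support_sigmas·width`` and must
    not overlap the pre-stimulus interval (t ≤ 0), so the waveform is exactly
    zero over the whole baseline.
    """
    times = np.asarray(times, float)
    if morphology is not None:
        if morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {morphology!r}")
        lat0, amp0, wid0 = MORPHOLOGIES[morphology]
        latencies = lat0 if latencies is None else latencies
        amplitudes = amp0 if amplitudes is None else amplitudes
        widths = wid0 if widths is None else widths
    latencies = np.asarray(latencies, float)
    amplitudes = np.asarray(amplitudes, float)
    widths = np.asarray(widths, float)
    if not latencies.shape == amplitudes.shape == widths.shape:
        raise ValueError("latencies, amplitudes, widths must align")
    w = np.zeros_like(times)
    t_end = times[-1]
    for lat, amp, sd in zip(latencies, amplitudes, widths):
        if amp == 0:
            continue
        lo, hi = lat - support_sigmas * sd, lat + support_sigmas * sd
        if lo <= 0:
            raise ValueError(
                f"lobe at {lat} ms (width {sd}) overlaps the baseline window")
        if lat >= t_end:
            raise ValueError(f"lobe latency {lat} ms beyond the epoch end")
        sel = (times >= lo) & (times <= hi)
        w[sel] += amp * np.exp(-0.5 * ((times[sel] - lat) / sd) ** 2)
    return w


def make_ci_artifact(times: np.ndarray, duration: float = 36.0,
                     amplitude: float = 500.0, carrier: float = 250.0,
                     fs: float = 1000.0, pedestal: float = 0.6) -> np.ndarray:
    """Biphasic pulse-train artifact occupying exactly [0, duration] ms.

    Pulses arrive at ``carrier`` per second; each is one positive sample
    immediately followed by one negative sample of equal magnitude, so every
    pulse integrates to ~0. On top of the charge-balanced train sits a
    baseline pedestal of ``pedestal × amplitude`` for the duration of the
    train, emulating the amplifier baseline shift that real implant
    stimulation produces — it is this low-frequency component, not the
    radio-frequency pulses, that survives band-limiting and makes artifact
    suppression necessary downstream. Zero outside the stimulus train.
    """
    times = np.asarray(times, float)
    if duration <= 0:
        raise ValueError("artifact duration must be positive")
    if duration > times[-1]:
        raise ValueError("artifact duration exceeds the epoch end")
    w = np.zeros_like(times)
    if amplitude == 0:
        return w
    dt = 1000.0 / fs
    period = 1000.0 / carrier
    onset = 0.0
    while onset < duration - dt / 2:
        i = int(np.searchsorted(times, onset - 1e-9))
        if i + 1 < times.size and times[i + 1] <= duration + 1e-9:
            w[i] += amplitude
            w[i + 1] -= amplitude
        onset += period
    w[(times >= 0.0) & (times <= duration)] += pedestal * amplitude
    return w


def artifact_topography(channel_positions: np.ndarray, side: str,
                        scalp_radius: float = 92.0,
                        spread_mm: float = 55.0) -> np.ndarray:
    """Rank-1 artifact spatial pattern concentrated over implant-side channels.

    Gaussian falloff with distance from a point over the implant (mastoid
    region), peak normalized to 1.
    """
    sgn = {"left": -1.0, "right": 1.0}[side]
    src = np.array([sgn * 0.85, -0.10, -0.30])
    src = src / np.linalg.norm(src) * scalp_radius
    d = np.linalg.norm(channel_positions - src, axis=1)
    topo = np.exp(-0.5 * (d / spread_mm) ** 2)
    return topo / topo.max()


def default_sources(config: SimulationConfig, *, amp_left: float,
                    amp_right: float, morphology: str | None = None):
    """Left/right auditory-cortex sources with tangential orientations."""
    times = epoch_times(config)
    morph = morphology or config.morphology
    wave = make_component_waveform(times, morph)
    out = []
    for loc, amp, label in ((LEFT_AC, amp_left, "left_AC"),
                            (RIGHT_AC, amp_right, "right_AC")):
        # tangential orientation: perpendicular to the radius, roughly
        # superior-anterior, as auditory cortex sources project to the vertex
        r = np.asarray(loc, float)
        r = r / np.linalg.norm(r)
        up = np.array([0.0, 0.3, 1.0])
        ori = up - (up @ r) * r
        out.append(SourceSpec(location=loc, orientation=tuple(ori),
                              waveform=amp * wave, label=label))
    return out


def simulate_epochs(config: SimulationConfig, sources, head: HeadModel = None,
                    *, artifact_sides=("right",), condition: str = "CI1",
                    rng: np.random.Generator | None = None,
                    metadata: dict | None = None) -> EpochSet:
    """Forward-project sources, add stimulus artifact and sensor noise.

    Data are referenced to the right-earlobe electrode exactly as acquired:
    potentials are computed at the 62 cephalic channels and at the reference
    position, and the reference potential is subtracted. Identical seed and
    config give bit-identical output.
    """
    head = head or build_head_model()
    times = epoch_times(config)
    names, chan_pos, ref_pos = standard_62_montage(head.scalp_radius)
    all_pos = np.vstack([chan_pos, ref_pos])

    signal = np.zeros((len(chan_pos), times.size))
    for src in sources:
        if src.waveform.size != times.size:
            raise ValueError("source waveform length must equal epoch length")
        lf = leadfield_for_dipoles(head, [src.location], [src.orientation],
                                   all_pos)[:, 0]
        lf = lf[:-1] - lf[-1]                     # earlobe reference
        signal += np.outer(lf, src.waveform)

    art = np.zeros_like(signal)
    if config.artifact_amplitude > 0:
        wave = make_ci_artifact(times, config.artifact_duration,
                                config.artifact_amplitude,
                                config.artifact_carrier, config.fs)
        for side in artifact_sides:
            topo = artifact_topography(chan_pos, side, head.scalp_radius)
            art += np.outer(topo, wave)

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd,
                       size=(len(chan_pos), times.size, config.n_epochs))
    data = (signal + art)[:, :, None] + noise
    meta = dict(metadata or {})
    meta.setdefault("artifact_sides", list(artifact_sides))
    return EpochSet(data=data, times=times, channel_positions=chan_pos,
                    fs=config.fs, reference="A2", condition=condition,
                    channel_names=names, metadata=meta)


# --------------------------------------------------------------------------
# longitudinal cohort generator
# --------------------------------------------------------------------------

@dataclass
class EffectModel:
    """Planted effect structure for the longitudinal generator.

    representation_pct(delay) = rep_intercept + rep_slope · (delay − 10.07),
    plus a per-participant random intercept; negative values mean the newly
    implanted (left) ear dominates. Second-implant and bilateral source
    amplitudes decay across sessions toward ``decay_asymptote`` while
    first-implant amplitudes stay constant. ``enhancement_left/right`` are
    bilateral-minus-ipsilateral source-amplitude differences in nA·m.
    """

    rep_intercept: float = -35.0        # % at the cohort-mean delay
    rep_slope: float = -9.0             # % per year of inter-implant delay
    random_intercept_sd: float = 8.0    # % between-participant spread
    delay_center: float = 10.07         # years; cohort mean
    hemisphere_bias: float = 0.25       # left-AC gain excess (lateralization ≈ −25%)
    total_amplitude: float = 120.0      # nA·m, CI1 + CI2 source budget per AC
    decay_rate: float = 0.9             # per session step
    decay_asymptote: float = 0.55
    enhancement_left: float = -20.0     # nA·m
    enhancement_right: float = 40.0     # nA·m


CONDITIONS = ("CI1", "CI2", "CIB")


def _session_decay(model: EffectModel, s: int) -> float:
    return model.decay_asymptote + (1 - model.decay_asymptote) * np.exp(
        -model.decay_rate * s)


def ground_truth_amplitudes(model: EffectModel, delay: float,
                            rand_intercept: float):
    """Per-session, per-condition, per-hemisphere source amplitudes (nA·m).

    Returns a list of dict rows with the planted ground truth.
    """
    rep0 = model.rep_intercept + model.rep_slope * (delay - model.delay_center)
    rep0 = float(np.clip(rep0 + rand_intercept, -95.0, 95.0))
    g = {"left": 1.0 + model.hemisphere_bias, "right": 1.0 - model.hemisphere_bias}
    w1 = (1.0 + rep0 / 100.0) / 2.0     # CI1 share of the amplitude budget
    w2 = (1.0 - rep0 / 100.0) / 2.0
    rows = []
    for s, tb in enumerate(TimeBin):
        f = _session_decay(model, s)
        for hemi in ("left", "right"):
            a1 = model.total_amplitude * g[hemi] * w1
            a2 = model.total_amplitude * g[hemi] * w2 * f
            ipsi = a2 if hemi == "left" else a1   # left AC ipsi ear = left = CI2
            enh = (model.enhancement_left if hemi == "left"
                   else model.enhancement_right)
            ab = max(ipsi + enh * g[hemi] * (f if hemi == "left" else 1.0), 0.0)
            rows.append(dict(
                session=s, time_bin=tb.value, hemisphere=hemi,
                amp_CI1=a1, amp_CI2=a2, amp_CIB=ab,
                true_representation=100.0 * (a1 - a2) / (a1 + a2),
                true_enhancement=ab - ipsi,
            ))
    return rows


def simulate_longitudinal_cohort(cohort: pd.DataFrame, effect_model: EffectModel,
                                 seed: int, config: SimulationConfig | None = None,
                                 head: HeadModel | None = None):
    """Simulate epochs for every participant × session × condition.

    Yields ``(participant_id, time_bin, condition, EpochSet)`` lazily to keep
    memory bounded, and exposes the planted ground truth via the returned
    generator's ``truth`` attribute (a tidy DataFrame built up front).
    """
    if effect_model is None:
        raise ValueError("effect_model is required")
    config = config or SimulationConfig()
    head = head or build_head_model()
    rng = np.random.default_rng(seed)

    truth_rows = []
    plan = []
    for _, p in cohort.iterrows():
        b_i = (rng.normal(0.0, effect_model.random_intercept_sd)
               if effect_model.random_intercept_sd > 0 else 0.0)
        rows = ground_truth_amplitudes(effect_model, float(p["inter_implant_delay"]), b_i)
        for r in rows:
            r = dict(r, participant_id=p["participant_id"],
                     inter_implant_delay=float(p["inter_implant_delay"]),
                     age_ci1=float(p["age_ci1"]))
            truth_rows.append(r)
        plan.append(p["participant_id"])
    truth = pd.DataFrame(truth_rows)

    def gen():
        for pid in plan:
            tp = truth[truth["participant_id"] == pid]
            for s, tb in enumerate(TimeBin):
                trow = {h: tp[(tp["session"] == s) & (tp["hemisphere"] == h)].iloc[0]
                        for h in ("left", "right")}
                for cond in CONDITIONS:
                    amp_l = float(trow["left"][f"amp_{cond}"])
                    amp_r = float(trow["right"][f"amp_{cond}"])
                    morph = "mature_P1N1P2" if cond == "CI1" else "immature_NciPci"
                    sources = default_sources(config, amp_left=amp_l,
                                              amp_right=amp_r, morphology=morph)
                    sides = {"CI1": ("right",), "CI2": ("left",),
                             "CIB": ("left", "right")}[cond]
                    epochs = simulate_epochs(
                        config, sources, head, artifact_sides=sides,
                        condition=cond, rng=rng,
                        metadata=dict(participant_id=pid, time_bin=tb.value,
                                      session=s))
                    yield pid, tb, cond, epochs

    g = gen()
    g = _TruthGenerator(g, truth)
    return g


class _TruthGenerator:
    """Iterator over simulated datasets carrying the ground-truth table."""

    def __init__(self, gen, truth: pd.DataFrame):
        self._gen = gen
        self.truth = truth

    def __iter__(self):
        return self._gen


def simulate_speech_scores(true_ability, n_words: int, seed: int) -> dict:
    """Binomial percent-words-correct scores per ear/condition.

    ``true_ability`` maps condition labels to probabilities in [0, 1].
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for key, p in true_ability.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"ability for {key!r} outside [0, 1]: {p}")
        out[key] = 100.0 * rng.binomial(n_words, p) / n_words
    return out
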