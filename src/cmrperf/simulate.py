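"""Synthetic first-pass perfusion cohorts with known ground truth.

Nothing in a patient study can serve as ground truth for flow, so every
pipeline stage is exercised against simulated cohorts built here:

* the arterial input is a gamma-variate first pass plus a delayed,
  dispersed recirculation peak, shaped so the trough between the two lands
  in the clinically typical 20-35 frame range at one frame per second;
* tissue curves are exact distributed-parameter responses to that input,
  with per-segment ground-truth kinetics drawn around healthy hyperaemic
  (MBF ~ 3.2 mL/min/mL) and resting (~1.2 mL/min/mL) values;
* curves are rendered to scanner signal through the saturation-recovery
  FLASH forward model, with an extra multiplicative T2* attenuation term
  exp(-TE * r2* * c(t)). The analysis stage knows nothing about this term,
  so at main-bolus dose the converted blood-pool curve under-reads its true
  peak — the residual AIF saturation that motivates dual-bolus protocols —
  while the 5x-dilute pre-bolus is nearly unaffected;
* dual-bolus acquisitions pair a dilute pre-bolus (1:5 dose ratio) with the
  full-dose main bolus under one calibration.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .curves import AIF_LABEL, ConcentrationCurve, SignalCurve
from .kinetics import DPParams, dp_forward
from .signal import AcquisitionParams, Calibration, forward_signal

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "DualBolusAcquisition",
    "generate_aif",
    "generate_tissue",
    "render_signal",
    "generate_cohort",
    "generate_dual_bolus",
    "draw_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants for the synthetic cohort.

    Defaults emulate a 3T adenosine stress protocol: 50 dynamic frames at
    one frame per cardiac cycle (dt = 1 s), a main-bolus blood-pool peak of
    about 4 mM, and a 1:5 pre-bolus:main-bolus dose ratio (dose_scale 0.2
    for the pre-bolus). ``r2_star`` sets the strength of the T2*
    attenuation responsible for residual AIF saturation; 0 disables it.
    """

    seed: int = 0
    dt: float = 1.0  # s per dynamic frame
    n_frames: int = 50
    # arterial input shape
    aif_amplitude: float = 4.0  # mM, main-bolus first-pass peak
    onset: float = 8.0  # s, bolus arrival
    gamma_shape: float = 3.2
    gamma_scale: float = 1.9  # s
    recirc_delay: float = 14.0  # s after first-pass onset
    recirc_fraction: float = 0.35  # recirculation peak / first-pass peak
    recirc_broadening: float = 2.6  # recirc gamma-scale multiplier
    dose_scale: float = 1.0  # 1.0 = main bolus, 0.2 = pre-bolus (1:5)
    prebolus_onset_shift: float = -2.0  # s, pre-bolus arrives earlier
    # signal rendering
    r2_star: float = 20.0  # /mM/s, T2* attenuation strength (0 disables)
    noise_sd: float = 0.010  # receiver noise SD on tissue curves, fraction of psi
    aif_noise_sd: float = 0.004  # receiver noise SD on blood-pool curves
    prebolus_shape_jitter: float = 0.25  # between-injection bolus shape variation
    psi_true: float = 1000.0  # planted scanner constant, signal units
    native_t1_blood: float = 1.7  # s at 3T
    native_t1_tissue: float = 1.2  # s at 3T
    n_baseline: int = 5
    # ground-truth kinetic ranges (uniform draws), per state
    mbf_stress: Tuple[float, float] = (3.2, 0.45)  # mean, sd (normal draw)
    mbf_rest: Tuple[float, float] = (1.2, 0.2)
    t_overall_stress: Tuple[float, float] = (9.0, 15.0)
    t_overall_rest: Tuple[float, float] = (22.0, 36.0)
    t_cap_stress: Tuple[float, float] = (2.0, 4.0)
    t_cap_rest: Tuple[float, float] = (4.0, 8.0)
    t_int_stress: Tuple[float, float] = (8.0, 20.0)
    t_int_rest: Tuple[float, float] = (20.0, 50.0)

    def __post_init__(self) -> None:
        if self.n_frames < 40:
            raise ValueError(f"n_frames must be >= 40, got {self.n_frames}")
        if not (0 <= self.recirc_fraction < 1):
            raise ValueError("recirc_fraction must be in [0, 1)")
        if self.dose_scale <= 0:
            raise ValueError("dose_scale must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class GroundTruth:
    """Everything needed to score a fit of the generated data."""

    truths: Dict[Tuple[str, str, int], DPParams]  # (subject, state, segment)
    aif_true: Dict[Tuple[str, str], ConcentrationCurve]  # (subject, state)
    config: SimulationConfig
    calibrations: Dict[str, Calibration] = field(default_factory=dict)


@dataclass
class Cohort:
    aifs: Dict[Tuple[str, str], ConcentrationCurve]
    tissues: Dict[Tuple[str, str, int], ConcentrationCurve]
    truth: GroundTruth

    @property
    def n_tissue_curves(self) -> int:
        return len(self.tissues)


@dataclass
class DualBolusAcquisition:
    """One subject-state dual-bolus acquisition, signal and truth domains."""

    prebolus_aif: SignalCurve
    main_aif: SignalCurve
    tissue_signals: Dict[int, SignalCurve]
    true_main_aif: ConcentrationCurve
    true_prebolus_aif: ConcentrationCurve
    true_tissues: Dict[int, ConcentrationCurve]
    truths: Dict[int, DPParams]
    blood_calibration: Calibration
    tissue_calibration: Calibration


def _gamma_variate(t: np.ndarray, onset: float, shape: float, scale: float) -> np.ndarray:
    """Gamma-variate bolus shape normalized to unit peak."""
    tau = np.clip(t - onset, 0.0, None) / scale
    # tau**shape * exp(-tau) peaks at tau = shape; rescaled so the peak is 1
    g = (tau / shape) ** shape * np.exp(shape - tau)
    g[t <= onset] = 0.0
    return g


def generate_aif(cfg: SimulationConfig) -> ConcentrationCurve:
    """True (unsaturated) arterial concentration curve.

    First pass plus recirculation; the peak scales exactly linearly with
    ``dose_scale``. Deterministic — noise enters only at signal rendering.
    """
    t = cfg.dt * np.arange(cfg.n_frames)
    first = _gamma_variate(t, cfg.onset, cfg.gamma_shape, cfg.gamma_scale)
    recirc = _gamma_variate(
        t,
        cfg.onset + cfg.recirc_delay,
        cfg.gamma_shape,
        cfg.gamma_scale * cfg.recirc_broadening,
    )
    values = cfg.aif_amplitude * cfg.dose_scale * (first + cfg.recirc_fraction * recirc)
    return ConcentrationCurve(times=t, values=values, region_label=AIF_LABEL)


def generate_tissue(aif: ConcentrationCurve, truth: DPParams) -> ConcentrationCurve:
    """Exact distributed-parameter tissue response to ``aif``."""
    return dp_forward(aif, truth)


def render_signal(
    conc: ConcentrationCurve,
    cal: Calibration,
    params: AcquisitionParams,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    noise_sd: Optional[float] = None,
) -> SignalCurve:
    """Render a concentration curve to scanner signal.

    SI(t) = forward(1/T1_native + r1 c(t)) * exp(-TE r2* c(t)) + noise.
    Receiver noise is Gaussian with a constant SD of ``noise_sd`` times the
    scanner constant Psi — constant in signal units, as thermal coil noise
    is, so dilute curves carry proportionally more relative noise.
    ``noise_sd`` defaults to ``cfg.noise_sd`` (the tissue-ROI level; pass
    ``cfg.aif_noise_sd`` for the larger, quieter blood-pool ROI).

    With ``r2_star`` = 0 and no noise the conversion stage inverts this
    exactly; with ``r2_star`` > 0 the attenuation is invisible to the
    analysis and survives as concentration underestimation at high dose.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    c = np.clip(conc.values, 0.0, None)
    r1 = 1.0 / cal.native_t1 + params.r1_relaxivity * c
    si = forward_signal(r1, params, cal.psi) * np.exp(-params.te * cfg.r2_star * c)
    if sd > 0:
        si = si + rng.normal(0.0, sd * cal.psi, size=si.shape)
    si = np.clip(si, 1e-9 * cal.psi, None)
    return SignalCurve(times=conc.times.copy(), values=si, region_label=conc.region_label)


def draw_truth(rng: np.random.Generator, cfg: SimulationConfig, state: str) -> DPParams:
    """Draw one segment's ground-truth kinetics for the given state."""
    if state == "stress":
        mu, sd = cfg.mbf_stress
        t_rng, tc_rng, te_rng = cfg.t_overall_stress, cfg.t_cap_stress, cfg.t_int_stress
    elif state == "rest":
        mu, sd = cfg.mbf_rest
        t_rng, tc_rng, te_rng = cfg.t_overall_rest, cfg.t_cap_rest, cfg.t_int_rest
    else:
        raise ValueError(f"state must be stress|rest, got {state!r}")
    mbf = float(np.clip(rng.normal(mu, sd), 0.3, 8.0))
    t_overall = float(rng.uniform(*t_rng))
    t_cap = float(min(rng.uniform(*tc_rng), 0.9 * t_overall))
    t_int = float(rng.uniform(*te_rng))
    return DPParams(mbf=mbf, t_overall=t_overall, t_cap=t_cap, t_int=t_int)


def generate_cohort(
    n_subjects: int,
    n_segments: int = 16,
    states: Tuple[str, ...] = ("stress", "rest"),
    cfg: Optional[SimulationConfig] = None,
) -> Cohort:
    """Ground-truth concentration-domain cohort.

    One arterial input per subject and state (with a small per-subject
    amplitude variation) and ``n_segments`` tissue curves each, all exact
    model responses. 13 subjects x 16 segments x 2 states reproduces the
    416-curve shape of a full stress/rest study.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    aifs: Dict[Tuple[str, str], ConcentrationCurve] = {}
    tissues: Dict[Tuple[str, str, int], ConcentrationCurve] = {}
    truths: Dict[Tuple[str, str, int], DPParams] = {}
    for i in range(n_subjects):
        subj = f"S{i + 1:02d}"
        amp_jitter = float(rng.uniform(0.85, 1.15))
        for state in states:
            sub_cfg = replace(
                cfg, aif_amplitude=cfg.aif_amplitude * amp_jitter
            )
            aif = generate_aif(sub_cfg)
            aifs[(subj, state)] = aif
            for seg in range(1, n_segments + 1):
                truth = draw_truth(rng, cfg, state)
                tissues[(subj, state, seg)] = generate_tissue(aif, truth)
                truths[(subj, state, seg)] = truth
    return Cohort(
        aifs=aifs,
        tissues=tissues,
        truth=GroundTruth(truths=truths, aif_true=dict(aifs), config=cfg),
    )


def generate_dual_bolus(
    cfg: SimulationConfig,
    n_segments: int = 16,
    state: str = "stress",
    params: Optional[AcquisitionParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> DualBolusAcquisition:
    """One subject's dual-bolus acquisition rendered to scanner signal.

    The pre-bolus is injected at ``dose_scale / 5`` (the 1:5 protocol),
    arriving ``prebolus_onset_shift`` seconds earlier. Because it is a
    separate injection under continuing vasodilation, its normalized bolus
    shape differs from the main bolus: shape, width, recirculation fraction
    and delay are each perturbed by up to ``prebolus_shape_jitter``
    (relative) per acquisition. Blood-pool curves are rendered with
    ``aif_noise_sd``, tissue curves with ``noise_sd``, under one
    calibration per region class (blood vs myocardium), so the dual-bolus
    analysis path can scale and align the pre-bolus exactly as it would on
    patient data.
    """
    params = params or AcquisitionParams()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    blood_cal = Calibration(
        psi=cfg.psi_true, native_t1=cfg.native_t1_blood, n_baseline=cfg.n_baseline
    )
    tissue_cal = Calibration(
        psi=cfg.psi_true, native_t1=cfg.native_t1_tissue, n_baseline=cfg.n_baseline
    )
    main_true = generate_aif(cfg)
    jit = cfg.prebolus_shape_jitter
    pre_cfg = replace(
        cfg,
        dose_scale=cfg.dose_scale / 5.0,
        onset=cfg.onset + cfg.prebolus_onset_shift,
        gamma_shape=cfg.gamma_shape * float(rng.uniform(1 - jit, 1 + jit)),
        gamma_scale=cfg.gamma_scale * float(rng.uniform(1 - jit, 1 + jit)),
        recirc_fraction=min(
            cfg.recirc_fraction * float(rng.uniform(1 - jit, 1 + jit)), 0.9
        ),
        recirc_delay=cfg.recirc_delay + float(rng.uniform(-2.0, 2.0)) * (jit > 0),
    )
    pre_true = generate_aif(pre_cfg)
    truths: Dict[int, DPParams] = {}
    true_tissues: Dict[int, ConcentrationCurve] = {}
    tissue_signals: Dict[int, SignalCurve] = {}
    for seg in range(1, n_segments + 1):
        truth = draw_truth(rng, cfg, state)
        truths[seg] = truth
        tiss = generate_tissue(main_true, truth)
        tiss.region_label = f"seg{seg:02d}"
        true_tissues[seg] = tiss
        tissue_signals[seg] = render_signal(
            tiss, tissue_cal, params, cfg, rng, noise_sd=cfg.noise_sd
        )
    return DualBolusAcquisition(
        prebolus_aif=render_signal(
            pre_true, blood_cal, params, cfg, rng, noise_sd=cfg.aif_noise_sd
        ),
        main_aif=render_signal(
            main_true, blood_cal, params, cfg, rng, noise_sd=cfg.aif_noise_sd
        ),
        tissue_signals=tissue_signals,
        true_main_aif=main_true,
        true_prebolus_aif=pre_true,
        true_tissues=true_tissues,
        truths=truths,
        blood_calibration=blood_cal,
        tissue_calibration=tissue_cal,
    )
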