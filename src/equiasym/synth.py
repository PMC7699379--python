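"""Synthetic gait trajectories and observer score tables with known truth.

No motion-capture or pain-assessment data from the induction study were
deposited, so every downstream stage is exercised against this generator,
which emulates the study's structure: 8 horses, a baseline occasion plus
several post-induction occasions whose movement asymmetry rises to an
individual maximum and then declines, and 3 observers scoring 37 items
from four pain scales at each assessment.

Gait signal model
-----------------
The pelvis (and analogously the poll) vertical displacement over a stride
of period ``T = 1/f`` is the sum of two phase-locked sinusoids::

    z(t) = A * cos(2 * w * t) + (d / 2) * sin(w * t),   w = 2 * pi * f

With ``x = sin(w t)`` this is the quadratic ``A - 2 A x**2 + (d/2) x``, so
for ``|d| < 4 A`` the two displacement minima per stride sit exactly at
``w t = pi/2`` and ``3 pi/2`` with values ``-A + d/2`` and ``-A - d/2``:
the right-minus-left minima difference equals ``d`` in closed form, which
makes the injected asymmetry exact ground truth.  Pelvic roll is a
one-per-stride sinusoid phase-locked so that it is positive during the
right-stance half-stride (the side convention shared with
:mod:`equiasym.kinematics`).

Score model
-----------
Scores follow a thresholded-Gaussian ordinal model: each observer's latent
value is ``item_effect * normalized_asymmetry + horse_effect + noise`` and
is cut into the item's score range by strictly increasing per-scale
thresholds.  Items with zero effect are pure noise; the returned ground
truth records which items carry signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kinematics import MarkerTrajectorySet, ParameterError
from .scales import ScaleItem

__all__ = [
    "GaitParams",
    "TrialDesign",
    "GroundTruth",
    "simulate_gait",
    "simulate_scores",
    "default_design",
    "DEFAULT_ITEM_EFFECTS",
    "default_thresholds",
]

#: Latent effect sizes (in latent-noise sd units at maximum asymmetry) for
#: the items the generator couples to movement asymmetry.  The choice
#: emulates the study system: posture-related behaviors are the strongest
#: predictors, followed by focus, temperature and orbital tightening.
DEFAULT_ITEM_EFFECTS: dict[tuple[str, str], float] = {
    ("EPS", "pos"): 3.0,
    ("CPS", "pos"): 3.0,
    ("CPS", "temp"): 3.0,
    ("EQUUS_FAP", "focus"): 2.5,
    ("HGS", "orb"): 2.0,
    ("CPS", "hr"): 2.0,
    ("EPS", "loc"): 1.5,
    ("EPS", "int"): 1.5,
    ("EQUUS_FAP", "fleya"): 1.5,
    ("EPS", "head"): 1.0,
}


def default_thresholds() -> dict[str, list[float]]:
    """Default ordinal cut points per scale (latent units).

    A latent value below 0.5 maps to score 0; each further unit crosses
    one threshold, so strong items (effect ~3) reach the upper scores at
    peak asymmetry while null items mostly stay at 0.
    """
    return {
        "HGS": [0.5, 1.5],
        "EQUUS_FAP": [0.5, 1.5],
        "EPS": [0.5, 1.5, 2.5, 3.5],
        "CPS": [0.5, 1.5, 2.5],
    }


@dataclass
class GaitParams:
    """Parameters of one simulated straight-line trot measurement."""

    stride_frequency: float = 1.3      # Hz
    n_strides: int = 20
    sampling_rate: float = 200.0       # Hz
    head_asym_mm: float = 0.0          # HDmin ground truth; negative = left-sided
    pelvis_asym_mm: float = 0.0        # PDmin ground truth; negative = left-sided
    base_amplitude_mm: float = 40.0    # half peak-to-peak of the 2/stride component
    noise_sd_mm: float = 0.0
    roll_amplitude_deg: float = 3.0
    yaw_amplitude_deg: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.stride_frequency <= 0:
            raise ParameterError("stride_frequency must be positive")
        if self.sampling_rate < 20 * self.stride_frequency:
            raise ParameterError("sampling_rate must be at least 20x stride_frequency")
        if self.n_strides < 3:
            raise ParameterError("n_strides must be at least 3")
        if self.base_amplitude_mm <= 0:
            raise ParameterError("base_amplitude_mm must be positive")
        if self.noise_sd_mm < 0:
            raise ParameterError("noise_sd_mm must be non-negative")
        for d in (self.head_asym_mm, self.pelvis_asym_mm):
            if abs(d) / 2.0 >= 4 * self.base_amplitude_mm:
                raise ParameterError("asymmetry too large for the signal model")


def simulate_gait(params: GaitParams) -> MarkerTrajectorySet:
    """Simulate marker trajectories for one trot measurement.

    Fully reproducible from ``params.seed``.  The noise-free minima
    difference of the pelvis (poll) signal equals ``pelvis_asym_mm``
    (``head_asym_mm``) exactly, by the closed form in the module docstring.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    f = params.stride_frequency
    fs = params.sampling_rate
    n = int(round(params.n_strides / f * fs)) + 1
    t = np.arange(n) / fs
    w = 2 * np.pi * f
    A = params.base_amplitude_mm

    def displacement(asym: float) -> np.ndarray:
        return A * np.cos(2 * w * t) + (asym / 2.0) * np.sin(w * t)

    sacrale = displacement(params.pelvis_asym_mm)
    poll = displacement(params.head_asym_mm)
    # positive during the right-stance half-stride (w t in [0, pi])
    roll = params.roll_amplitude_deg * np.sin(w * t)
    yaw = params.yaw_amplitude_deg * np.cos(w * t)
    # tubera coxae: midline motion plus an antisymmetric roll contribution
    tc_gain = 5.0  # mm per degree of roll
    left_tc = sacrale + tc_gain * roll
    right_tc = sacrale - tc_gain * roll
    if params.noise_sd_mm > 0:
        sacrale = sacrale + rng.normal(0, params.noise_sd_mm, n)
        poll = poll + rng.normal(0, params.noise_sd_mm, n)
        left_tc = left_tc + rng.normal(0, params.noise_sd_mm, n)
        right_tc = right_tc + rng.normal(0, params.noise_sd_mm, n)
    return MarkerTrajectorySet(
        time=t,
        poll_z=poll,
        sacrale_z=sacrale,
        left_tc_z=left_tc,
        right_tc_z=right_tc,
        roll=roll,
        yaw=yaw,
        sampling_rate=fs,
    )


@dataclass
class TrialDesign:
    """Structure of a simulated induction study.

    ``asymmetry_trajectory`` maps each horse id to its per-occasion true
    total-asymmetry-score sequence (mm), starting near 0 at baseline and
    rising to an individual interior maximum before declining.
    ``item_effects`` maps ``(scale_id, item_id)`` to the latent effect at
    maximum asymmetry; unlisted items are null.
    """

    n_horses: int = 8
    n_observers_per_assessment: int = 3
    occasions_per_horse: int = 5      # baseline + >= 3 post-induction
    asymmetry_trajectory: dict[str, list[float]] = field(default_factory=dict)
    induced_side: dict[str, str] = field(default_factory=dict)
    item_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_EFFECTS)
    )
    observer_noise_sd: float = 1.0
    horse_effect_sd: float = 0.3
    ordinal_thresholds: dict[str, list[float]] = field(default_factory=default_thresholds)
    second_trot_prob: float = 0.25
    seed: int = 0

    @property
    def horses(self) -> list[str]:
        return [f"h{i + 1}" for i in range(self.n_horses)]

    @property
    def occasions(self) -> list[str]:
        return ["b0"] + [f"p{i + 1}" for i in range(self.occasions_per_horse - 1)]

    def validate(self) -> None:
        if self.occasions_per_horse < 4:
            raise ParameterError("need baseline plus at least 3 post-induction occasions")
        for horse, traj in self.asymmetry_trajectory.items():
            if len(traj) != self.occasions_per_horse:
                raise ParameterError(f"trajectory length mismatch for {horse}")
            if abs(traj[0]) > 1e-9:
                raise ParameterError(f"trajectory must start at 0 for {horse}")
            if max(traj) <= 0:
                raise ParameterError(f"trajectory must attain a positive maximum for {horse}")
        for scale, cuts in self.ordinal_thresholds.items():
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ParameterError(f"ordinal thresholds for {scale} not strictly increasing")


def default_design(seed: int = 0, **overrides) -> TrialDesign:
    """Build a :class:`TrialDesign` emulating the study conditions.

    Per horse, the true total asymmetry score rises from 0 at baseline to
    an individual peak (mean 61 mm, sd 24 mm, floored at 15 mm) at a
    randomly chosen interior occasion and declines back towards baseline;
    three left and five right hindlimbs are induced on average.
    """
    design = TrialDesign(seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    n_occ = design.occasions_per_horse
    for horse in design.horses:
        peak = max(15.0, rng.normal(61.0, 24.0))
        peak_idx = int(rng.integers(2, n_occ - 1))  # interior post-induction occasion
        traj = np.zeros(n_occ)
        for i in range(1, n_occ):
            if i <= peak_idx:
                traj[i] = peak * i / peak_idx
            else:
                traj[i] = peak * max(0.15, 1.0 - 0.45 * (i - peak_idx))
        design.asymmetry_trajectory[horse] = traj.tolist()
        design.induced_side[horse] = "left" if rng.random() < 3 / 8 else "right"
    design.validate()
    return design


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery testing."""

    item_effects: dict[tuple[str, str], float]
    asymmetry_trajectory: dict[str, list[float]]
    induced_side: dict[str, str]
    normalization_mm: float
    observer_assignment: dict[str, list[str]]
    seed: int


def _observer_panel(design: TrialDesign, rng: np.random.Generator) -> dict[str, list[str]]:
    """Observers 1 and 2 attend every assessment; the remaining slots
    rotate between horses, as in the study."""
    m = design.n_observers_per_assessment
    if m <= 2:
        return {h: [f"o{k + 1}" for k in range(m)] for h in design.horses}
    rotating_pool = ["o3", "o4", "o5"]
    panel = {}
    for h in design.horses:
        extra = list(rng.choice(rotating_pool, size=m - 2, replace=False))
        panel[h] = ["o1", "o2"] + sorted(extra)
    return panel


def simulate_scores(
    design: TrialDesign,
    scales: list[ScaleItem],
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the long-format ordinal score table for a whole study.

    One row per horse x occasion x phase (pre/post) x observer x item.
    Latent values use the occasion's true asymmetry normalized by the
    study-wide maximum, so effects are expressed "per unit of maximum
    asymmetry".  Returns the table and the injected ground truth.
    """
    design.validate()
    for key in design.item_effects:
        if not any((it.scale_id, it.item_id) == key for it in scales):
            raise ParameterError(f"item_effects references unknown item {key}")
    for it in scales:
        cuts = design.ordinal_thresholds.get(it.scale_id)
        if cuts is None or len(cuts) != it.max_score:
            raise ParameterError(
                f"ordinal thresholds for {it.scale_id} must have {it.max_score} cut points"
            )
    rng = np.random.default_rng(design.seed)
    panel = _observer_panel(design, rng)
    norm = max(max(t) for t in design.asymmetry_trajectory.values())
    horse_effects = {
        h: rng.normal(0, design.horse_effect_sd) if design.horse_effect_sd > 0 else 0.0
        for h in design.horses
    }
    effects_vec = np.array(
        [design.item_effects.get((it.scale_id, it.item_id), 0.0) for it in scales]
    )
    cuts_by_item = [np.asarray(design.ordinal_thresholds[it.scale_id]) for it in scales]
    n_items = len(scales)
    rows = []
    for hi, horse in enumerate(design.horses):
        # per-horse substream at a fixed offset, independent of other horses
        hrng = np.random.default_rng(design.seed + 10_000 + hi)
        traj = design.asymmetry_trajectory[horse]
        for oi, occ in enumerate(design.occasions):
            a_norm = traj[oi] / norm
            for phase in ("pre", "post"):
                for obs in panel[horse]:
                    latent = effects_vec * a_norm + horse_effects[horse]
                    if design.observer_noise_sd > 0:
                        latent = latent + hrng.normal(0, design.observer_noise_sd, n_items)
                    for k, it in enumerate(scales):
                        score = int(np.sum(latent[k] > cuts_by_item[k]))
                        rows.append(
                            (horse, occ, phase, obs, it.scale_id, it.item_id, score)
                        )
    table = pd.DataFrame(
        rows, columns=["horse", "occasion", "phase", "observer", "scale", "item", "score"]
    )
    truth = GroundTruth(
        item_effects=dict(design.item_effects),
        asymmetry_trajectory={h: list(t) for h, t in design.asymmetry_trajectory.items()},
        induced_side=dict(design.induced_side),
        normalization_mm=float(norm),
        observer_assignment=panel,
        seed=design.seed,
    )
    return table, truth
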