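"""Synthetic forced-oscillation study generator.

Builds a complete in-silico instillation study — factorial animal roster,
per-animal ground-truth mechanics, multi-sine ventilator waveforms, pooled
qPCR CT tables and BAL cell differentials — so that every downstream stage
(impedance estimation, model fitting, group statistics, BAL quantification)
can be exercised without any experimental data.

The forward waveform model inverts the input-impedance relation
``Z(f) = P(f) / V'(f)``: flow is a sum of sinusoids at the perturbation
frequencies and pressure is the PEEP baseline plus each tone scaled and
phase-shifted by ``Z(f) = RL(f) - i EL(f)/(2 pi f)`` (elastic reactance
negative), plus optional Gaussian sensor noise.  The mechanics model is the
heterogeneous lung-function parameterisation

    RL(f) = (a + b f) / (c + f)        EL(f) = E0 + dE (1 - exp(-beta f))

with f in Hz throughout (beta therefore in 1/Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MechParams",
    "StudyDesign",
    "EffectTemplate",
    "WaveformRecord",
    "DEFAULT_FREQUENCIES",
    "DEFAULT_BASE_PARAMS",
    "GENES",
    "CELL_TYPES",
    "build_design",
    "default_effect_template",
    "sample_animal_params",
    "synthesize_waveform",
    "simulate_ct_table",
    "simulate_differentials",
    "simulate_fit_table",
    "predict_rl",
    "predict_el",
    "impedance_of",
]

#: Perturbation tone set: 13 mutually prime multiples of 0.5 Hz spanning
#: 0.5-20.5 Hz, so that every tone completes an integer number of cycles
#: within any whole multiple of the 2 s fundamental period and the sinusoid
#: regressors are mutually orthogonal over the record.
DEFAULT_FREQUENCIES: tuple[float, ...] = tuple(
    0.5 * k for k in (1, 2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 37, 41)
)

GENES: tuple[str, ...] = ("CCL2", "IL1B", "IL6", "CXCL10", "IL10", "IL12B")
CELL_TYPES: tuple[str, ...] = ("macrophage", "neutrophil", "lymphocyte", "eosinophil")

PARAM_FIELDS: tuple[str, ...] = ("a", "b", "c", "e0", "de", "beta")


@dataclass(frozen=True)
class MechParams:
    """Six parameters of one lung's resistance/elastance spectra.

    Units: a in cmH2O.s/mL.Hz, b in cmH2O.s/mL (high-frequency resistance
    asymptote), c in Hz, e0 in cmH2O/mL (inherent tissue stiffness), de in
    cmH2O/mL (magnitude of change in elastance), beta in 1/Hz (rate of
    change of elastance).  The low-frequency resistance is a/c.
    """

    a: float
    b: float
    c: float
    e0: float
    de: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0 and self.e0 > 0 and self.beta > 0):
            raise ValueError(
                "MechParams requires a > 0, c > 0, e0 > 0, beta > 0; got "
                f"a={self.a}, c={self.c}, e0={self.e0}, beta={self.beta}"
            )
        if self.b < 0:
            raise ValueError(f"MechParams requires b >= 0; got b={self.b}")
        for name in PARAM_FIELDS:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"MechParams field {name} is not finite")

    @property
    def a_over_c(self) -> float:
        """Low-frequency resistance RL(0) = a/c."""
        return self.a / self.c

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_FIELDS}

    def scaled(self, factors: Mapping[str, float]) -> "MechParams":
        """Multiply each field by ``factors.get(field, 1.0)``."""
        return MechParams(**{k: v * factors.get(k, 1.0) for k, v in self.as_dict().items()})


#: Plausible mouse-scale baseline used throughout the package; configuration,
#: not a physiological claim.
DEFAULT_BASE_PARAMS = MechParams(a=2.0, b=0.2, c=5.0, e0=20.0, de=10.0, beta=0.5)


def predict_rl(params: MechParams, freqs: np.ndarray) -> np.ndarray:
    """Resistance spectrum RL(f) = (a + b f)/(c + f)."""
    f = np.asarray(freqs, dtype=float)
    return (params.a + params.b * f) / (params.c + f)


def predict_el(params: MechParams, freqs: np.ndarray) -> np.ndarray:
    """Elastance spectrum EL(f) = E0 + dE (1 - exp(-beta f))."""
    f = np.asarray(freqs, dtype=float)
    return params.e0 + params.de * (1.0 - np.exp(-params.beta * f))


def impedance_of(params: MechParams, freqs: np.ndarray) -> np.ndarray:
    """Complex input impedance Z(f) = RL(f) - i EL(f)/(2 pi f)."""
    f = np.asarray(freqs, dtype=float)
    return predict_rl(params, f) - 1j * predict_el(params, f) / (2.0 * np.pi * f)


# ---------------------------------------------------------------------------
# Study design


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout treatment x dose x day x PEEP x animal.

    ``roster`` enumerates one row per animal with columns
    animal_id, treatment, dose_label, dose_ug_per_g, day.
    """

    treatments: tuple[str, ...]
    doses: tuple[tuple[str, float], ...]  # (label, ug particle / g body weight)
    days: tuple[int, ...]
    peeps: tuple[float, ...]
    n_per_group: int
    seed: int
    roster: pd.DataFrame = field(compare=False, repr=False, default=None)

    @property
    def groups(self) -> list[tuple[str, str, int]]:
        """All (treatment, dose_label, day) cells."""
        return [
            (t, dl, d)
            for t in self.treatments
            for dl, _ in self.doses
            for d in self.days
        ]


DEFAULT_DOSES: tuple[tuple[str, float], ...] = (("low", 0.05), ("high", 0.5))


def build_design(
    treatments: Sequence[str] = ("HBSS", "CB", "AgNP", "AgNO3"),
    doses: Mapping[str, float] | Sequence[tuple[str, float]] = DEFAULT_DOSES,
    days: Sequence[int] = (1, 3, 7),
    peeps: Sequence[float] = (0.0, 1.0, 3.0, 6.0),
    n_per_group: int = 5,
    seed: int = 0,
) -> StudyDesign:
    """Enumerate the full animal roster for a factorial study.

    Deterministic given its arguments: the roster is a plain enumeration and
    ``seed`` is only carried along to seed downstream sampling.
    """
    treatments = tuple(str(t) for t in treatments)
    if isinstance(doses, Mapping):
        doses = tuple(doses.items())
    doses = tuple((str(lbl), float(v)) for lbl, v in doses)
    days = tuple(int(d) for d in days)
    peeps = tuple(float(p) for p in peeps)

    if not treatments or not doses or not days or not peeps:
        raise ValueError("every factor set (treatments, doses, days, peeps) must be non-empty")
    if len(set(treatments)) != len(treatments):
        raise ValueError("treatment labels must be unique")
    dose_labels = [lbl for lbl, _ in doses]
    if len(set(dose_labels)) != len(dose_labels):
        raise ValueError("dose labels must be unique")
    if len(doses) >= 2:
        values = [v for _, v in doses]
        if sorted(values) != values:
            raise ValueError("dose levels must be listed in increasing order (low < high)")
    if any(v <= 0 for _, v in doses):
        raise ValueError("dose levels must be positive")
    if not (1 <= int(n_per_group) <= 1000):
        raise ValueError(f"n_per_group must be in [1, 1000]; got {n_per_group}")

    rows = []
    for t in treatments:
        for dose_label, dose in doses:
            for day in days:
                for k in range(int(n_per_group)):
                    rows.append(
                        {
                            "animal_id": f"{t}-{dose_label}-d{day}-{k + 1:02d}",
                            "treatment": t,
                            "dose_label": dose_label,
                            "dose_ug_per_g": dose,
                            "day": day,
                        }
                    )
    roster = pd.DataFrame(rows)
    return StudyDesign(
        treatments=treatments,
        doses=doses,
        days=days,
        peeps=peeps,
        n_per_group=int(n_per_group),
        seed=int(seed),
        roster=roster,
    )


# ---------------------------------------------------------------------------
# Effect templates

GroupKey = tuple[str, str, int]  # (treatment, dose_label, day)

#: Resting BAL differential in untreated mice: macrophage-dominated.
CONTROL_PROPORTIONS: dict[str, float] = {
    "macrophage": 0.97,
    "neutrophil": 0.01,
    "lymphocyte": 0.01,
    "eosinophil": 0.01,
}


@dataclass(frozen=True)
class EffectTemplate:
    """Group-level ground truth for the simulated study.

    ``mech_shifts`` maps (treatment, dose_label, day) to multiplicative
    shifts on MechParams fields (missing field => 1.0); ``gene_folds`` to
    true fold expression relative to the control (missing gene => 1.0);
    ``cell_props`` to expected BAL differential proportions (missing group
    => control proportions).  The control treatment always has shift 1 and
    fold 1.
    """

    mech_shifts: Mapping[GroupKey, Mapping[str, float]] = field(default_factory=dict)
    gene_folds: Mapping[GroupKey, Mapping[str, float]] = field(default_factory=dict)
    cell_props: Mapping[GroupKey, Mapping[str, float]] = field(default_factory=dict)
    control_treatment: str = "HBSS"

    def __post_init__(self) -> None:
        for key, shifts in self.mech_shifts.items():
            if key[0] == self.control_treatment and any(v != 1.0 for v in shifts.values()):
                raise ValueError(f"control group {key} must have all mech shifts = 1.0")
            if any(v <= 0 for v in shifts.values()):
                raise ValueError(f"mech shifts must be positive; offending group {key}")
        for key, folds in self.gene_folds.items():
            if any(v <= 0 for v in folds.values()):
                raise ValueError(f"fold expression must be > 0; offending group {key}")
            if key[0] == self.control_treatment and any(v != 1.0 for v in folds.values()):
                raise ValueError(f"control group {key} must have fold 1.0 for every gene")
        for key, props in self.cell_props.items():
            if any(v < 0 for v in props.values()):
                raise ValueError(f"differential proportions must be >= 0; group {key}")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"differential proportions must sum to 1; group {key}")

    def mech_shift(self, key: GroupKey) -> dict[str, float]:
        shifts = dict.fromkeys(PARAM_FIELDS, 1.0)
        shifts.update(self.mech_shifts.get(key, {}))
        return shifts

    def fold(self, key: GroupKey, gene: str) -> float:
        return float(self.gene_folds.get(key, {}).get(gene, 1.0))

    def proportions(self, key: GroupKey) -> dict[str, float]:
        props = dict(CONTROL_PROPORTIONS)
        props.update(self.cell_props.get(key, {}))
        total = sum(props.values())
        return {k: v / total for k, v in props.items()}


def default_effect_template() -> EffectTemplate:
    """Treatment-effect template mirroring the reported time course.

    Qualitative pattern encoded: acute (day 1) AgNP stiffening (E0 up) with
    no CB mechanics effect; day-3 resolution of mechanics with CB
    neutrophilia and AgNP lymphocyte/macrophage influx plus a 60-fold IL10
    burst; day-7 AgNP decrease of E0 and low-frequency resistance a/c
    (shift 0.7 on both) with CCL2 still elevated (6-fold AgNP, 1.8-fold CB)
    and cytology largely resolved.  Carbon black never shifts mechanics.
    """
    hi = "high"
    mech = {
        ("AgNP", "low", 1): {"e0": 1.25},
        ("AgNP", hi, 1): {"e0": 1.3},
        ("AgNP", hi, 7): {"e0": 0.7, "a": 0.7},
        ("AgNO3", hi, 7): {},  # ionic silver: no mechanics effect
    }
    genes = {
        ("CB", hi, 1): {"IL1B": 4.0, "IL6": 4.0, "IL12B": 3.0},
        ("CB", hi, 3): {"IL1B": 3.0, "IL6": 3.0, "CCL2": 3.0, "IL10": 3.0},
        ("AgNP", hi, 3): {"IL1B": 3.0, "IL6": 3.0, "CCL2": 4.0, "IL10": 60.0},
        ("CB", hi, 7): {"CCL2": 1.8},
        ("AgNP", hi, 7): {"IL6": 1.8, "IL12B": 1.8, "IL10": 1.8, "CCL2": 6.0},
    }
    cells = {
        ("CB", hi, 1): {"macrophage": 0.73, "neutrophil": 0.25, "lymphocyte": 0.01, "eosinophil": 0.01},
        ("CB", hi, 3): {"macrophage": 0.83, "neutrophil": 0.15, "lymphocyte": 0.01, "eosinophil": 0.01},
        ("AgNP", hi, 3): {"macrophage": 0.87, "neutrophil": 0.02, "lymphocyte": 0.10, "eosinophil": 0.01},
        ("AgNP", hi, 7): {"macrophage": 0.96, "neutrophil": 0.015, "lymphocyte": 0.015, "eosinophil": 0.01},
    }
    return EffectTemplate(mech_shifts=mech, gene_folds=genes, cell_props=cells)


# ---------------------------------------------------------------------------
# Parameter sampling


def sample_animal_params(
    design: StudyDesign,
    template: EffectTemplate,
    base: MechParams = DEFAULT_BASE_PARAMS,
    cv: float = 0.15,
    rng: np.random.Generator | None = None,
) -> dict[str, MechParams]:
    """Draw per-animal ground-truth mechanics.

    Each field is ``base * group_shift * exp(N(0, sigma))`` with
    ``sigma = sqrt(log(1 + cv^2))`` so the multiplicative noise has
    geometric mean exactly 1 (cv=0 collapses to base * shift) and the
    parameters stay positive.
    """
    if not 0.0 <= cv <= 0.5:
        raise ValueError(f"cv must be in [0, 0.5]; got {cv}")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    out: dict[str, MechParams] = {}
    for row in design.roster.itertuples(index=False):
        key = (row.treatment, row.dose_label, row.day)
        shifts = template.mech_shift(key)
        noise = np.exp(rng.normal(0.0, sigma, size=len(PARAM_FIELDS))) if sigma > 0 else np.ones(len(PARAM_FIELDS))
        values = {
            name: getattr(base, name) * shifts[name] * noise[i]
            for i, name in enumerate(PARAM_FIELDS)
        }
        out[row.animal_id] = MechParams(**values)
    return out


# ---------------------------------------------------------------------------
# Waveform synthesis


@dataclass(frozen=True)
class WaveformRecord:
    """Sampled flow (mL/s) and airway pressure (cmH2O) for one animal at one PEEP."""

    animal_id: str
    peep: float
    sample_rate: float
    t: np.ndarray
    flow: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("t must be 1-D with at least 2 samples")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise ValueError("t must be strictly increasing")
        step = 1.0 / self.sample_rate
        if not np.allclose(dt, step, rtol=1e-9, atol=1e-12):
            raise ValueError("t must be uniformly sampled at 1/sample_rate")
        for name in ("flow", "pressure"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must have the same length as t")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def duration(self) -> float:
        return self.t.size / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "flow": self.flow, "pressure": self.pressure})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, animal_id: str, peep: float) -> "WaveformRecord":
        t = frame["t"].to_numpy(dtype=float)
        sample_rate = round(1.0 / float(np.median(np.diff(t))))
        return cls(
            animal_id=animal_id,
            peep=float(peep),
            sample_rate=float(sample_rate),
            t=t,
            flow=frame["flow"].to_numpy(dtype=float),
            pressure=frame["pressure"].to_numpy(dtype=float),
        )


def synthesize_waveform(
    params: MechParams,
    peep: float,
    freqs: Sequence[float] = DEFAULT_FREQUENCIES,
    duration: float = 8.0,
    sample_rate: float = 256.0,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
    amplitudes: Sequence[float] | None = None,
    phases: Sequence[float] | None = None,
    animal_id: str = "synthetic",
) -> WaveformRecord:
    """Forward-model one forced-oscillation maneuver.

    Flow is a multi-sine ``sum_f A_f sin(2 pi f t + phi_f)``; pressure is
    ``peep + sum_f |Z(f)| A_f sin(2 pi f t + phi_f + arg Z(f)) + N(0, noise_sd)``
    with ``Z(f) = RL(f) - i EL(f)/(2 pi f)``.  Each tone must complete an
    integer number of cycles within ``duration`` so that frequency-domain
    estimation is exact on the noiseless record.
    """
    freqs = np.asarray(list(freqs), dtype=float)
    if freqs.size == 0:
        raise ValueError("freqs must be non-empty")
    if len(np.unique(freqs)) != freqs.size:
        raise ValueError("duplicate perturbation frequencies")
    if duration <= 0:
        raise ValueError(f"duration must be positive; got {duration}")
    nyquist = sample_rate / 2.0
    bad = freqs[(freqs <= 0) | (freqs >= nyquist)]
    if bad.size:
        raise ValueError(f"frequencies outside (0, Nyquist={nyquist}): {bad.tolist()}")
    cycles = freqs * duration
    if not np.allclose(cycles, np.round(cycles), atol=1e-9):
        off = freqs[~np.isclose(cycles, np.round(cycles), atol=1e-9)]
        raise ValueError(f"duration must contain whole cycles of every tone; offending: {off.tolist()}")

    if rng is None:
        rng = np.random.default_rng(0)
    amps = np.ones_like(freqs) if amplitudes is None else np.asarray(list(amplitudes), dtype=float)
    if amps.shape != freqs.shape:
        raise ValueError("amplitudes must match freqs in length")
    if phases is None:
        phis = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    else:
        phis = np.asarray(list(phases), dtype=float)
        if phis.shape != freqs.shape:
            raise ValueError("phases must match freqs in length")

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    z = impedance_of(params, freqs)
    omega_t = 2.0 * np.pi * np.outer(freqs, t)  # (n_freqs, n_samples)
    flow = amps @ np.sin(omega_t + phis[:, None])
    pressure = peep + (amps * np.abs(z)) @ np.sin(omega_t + (phis + np.angle(z))[:, None])
    if noise_sd > 0:
        pressure = pressure + rng.normal(0.0, noise_sd, size=n)
    return WaveformRecord(
        animal_id=animal_id,
        peep=float(peep),
        sample_rate=float(sample_rate),
        t=t,
        flow=flow,
        pressure=pressure,
    )


# ---------------------------------------------------------------------------
# qPCR CT tables and BAL differentials


def simulate_ct_table(
    design: StudyDesign,
    template: EffectTemplate,
    ref_gene_ct: float = 20.0,
    base_ct: float = 26.0,
    genes: Sequence[str] = GENES,
    ct_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One pooled qPCR measurement per (group, gene).

    Samples within a treatment group are pooled before thermocycling, so
    the table carries a single CT per group and gene and no within-group
    variance.  The target CT encodes the template's true fold:
    ``ct_target = base_ct - log2(fold) + noise`` against a flat reference
    gene at ``ref_gene_ct``.
    """
    missing = set(GENES) - set(genes)
    if missing:
        raise ValueError(f"gene panel must include {sorted(missing)}")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    rows = []
    for key in design.groups:
        treatment, dose_label, day = key
        for gene in genes:
            fold = template.fold(key, gene)
            if fold <= 0:
                raise ValueError(f"true fold must be > 0; got {fold} for {key}/{gene}")
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append(
                {
                    "group": f"{treatment}-{dose_label}-d{day}",
                    "treatment": treatment,
                    "dose_label": dose_label,
                    "day": day,
                    "gene": gene,
                    "ct_target": base_ct - math.log2(fold) + noise,
                    "ct_reference": ref_gene_ct,
                }
            )
    return pd.DataFrame(rows)


def simulate_differentials(
    design: StudyDesign,
    template: EffectTemplate,
    total_cells: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multinomial cell-differential counts per animal over the four BAL cell types."""
    if total_cells < 1:
        raise ValueError(f"total_cells must be >= 1; got {total_cells}")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    rows = []
    for row in design.roster.itertuples(index=False):
        key = (row.treatment, row.dose_label, row.day)
        props = template.proportions(key)
        p = np.array([props[ct] for ct in CELL_TYPES], dtype=float)
        if np.any(p < 0):
            raise ValueError(f"negative differential proportion for group {key}")
        counts = rng.multinomial(total_cells, p / p.sum())
        rec = {
            "animal_id": row.animal_id,
            "treatment": row.treatment,
            "dose_label": row.dose_label,
            "day": row.day,
        }
        rec.update(dict(zip(CELL_TYPES, (int(x) for x in counts))))
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parameter-level study simulation (statistical calibration)


def simulate_fit_table(
    treatments: Sequence[str] = ("HBSS", "CB", "AgNP"),
    shifts: Mapping[str, Mapping[str, float]] | None = None,
    n_per_group: int = 5,
    cv: float = 0.15,
    cv_meas: float = 0.02,
    peeps: Sequence[float] = (0.0, 1.0, 3.0, 6.0),
    base: MechParams = DEFAULT_BASE_PARAMS,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a fitted-parameter table directly at the parameter level.

    Each animal draws its MechParams once (lognormal between-animal
    variation ``cv`` about base x treatment shift); each (animal, PEEP)
    measurement multiplies an independent lognormal factor ``cv_meas``
    standing in for estimation noise of the fitting stage.  Used for
    statistical calibration, where hundreds of simulated studies are needed
    and the waveform/fit stages are exercised elsewhere.

    Returns columns treatment, animal_id, peep, a, b, c, e0, de, beta, a_over_c.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    shifts = shifts or {}
    sigma_a = math.sqrt(math.log1p(cv * cv))
    sigma_m = math.sqrt(math.log1p(cv_meas * cv_meas))
    rows = []
    for t in treatments:
        shift = dict.fromkeys(PARAM_FIELDS, 1.0)
        shift.update(shifts.get(t, {}))
        for k in range(n_per_group):
            noise = np.exp(rng.normal(0.0, sigma_a, size=len(PARAM_FIELDS))) if sigma_a > 0 else np.ones(len(PARAM_FIELDS))
            truth = {
                name: getattr(base, name) * shift[name] * noise[i]
                for i, name in enumerate(PARAM_FIELDS)
            }
            for p in peeps:
                meas = np.exp(rng.normal(0.0, sigma_m, size=len(PARAM_FIELDS))) if sigma_m > 0 else np.ones(len(PARAM_FIELDS))
                rec = {"treatment": t, "animal_id": f"{t}-{k + 1:02d}", "peep": float(p)}
                rec.update({name: truth[name] * meas[i] for i, name in enumerate(PARAM_FIELDS)})
                rec["a_over_c"] = rec["a"] / rec["c"]
                rows.append(rec)
    return pd.DataFrame(rows)


def fundamental_frequency(freqs: Iterable[float]) -> float:
    """Greatest common divisor of the tone frequencies (Hz), via exact fractions."""
    fracs = [Fraction(f).limit_denominator(10**6) for f in freqs]
    g = fracs[0]
    for fr in fracs[1:]:
        g = Fraction(math.gcd(g.numerator, fr.numerator), math.lcm(g.denominator, fr.denominator))
    return float(g)
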