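"""Study-level calibration harnesses.

Convenience drivers used to audit the pipeline against its own simulator:
noiseless round-trip parameter recovery on an (a/c, E0) grid, type-I /
power calibration of the treatment-comparison machinery over many
simulated studies, and coverage of the residual-bootstrap intervals under
known noise.  These run the same public operations a user would call, just
in a loop.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .group_stats import compare_parameters
from .impedance import RESpectra
from .mechfit import bootstrap_ci, predict_spectra
from .pipeline import PipelineConfig, run_recovery_benchmark
from .synthetic_data import DEFAULT_BASE_PARAMS, DEFAULT_FREQUENCIES, MechParams, simulate_fit_table

__all__ = [
    "recovery_grid",
    "roundtrip_recovery",
    "family_rejection_rates",
    "agnp_detection_rates",
    "bootstrap_coverage",
]

#: Day-7 treatment effect: 30% drop of tissue stiffness and of
#: low-frequency resistance in the silver-nanoparticle group.
DAY7_AGNP_SHIFTS: dict[str, dict[str, float]] = {"AgNP": {"e0": 0.7, "a": 0.7}}


def recovery_grid(
    ac_values: Sequence[float] = (0.3, 0.45, 0.6),
    e0_values: Sequence[float] = (12.0, 20.0, 30.0),
    base: MechParams = DEFAULT_BASE_PARAMS,
) -> list[MechParams]:
    """3 x 3 grid over low-frequency resistance and tissue stiffness.

    a/c values stay away from b: at a = b c the resistance curve is exactly
    flat and (a, c) collapse to their ratio, so individual recovery is
    undefined there.
    """
    return [
        MechParams(**{**base.as_dict(), "a": base.c * ac, "e0": e0})
        for ac in ac_values
        for e0 in e0_values
    ]


def roundtrip_recovery(seed: int = 0, noise_sd: float = 0.0) -> pd.DataFrame:
    """Synthesize -> estimate impedance -> fit over the default recovery grid."""
    return run_recovery_benchmark(recovery_grid(), PipelineConfig(), noise_sd=noise_sd, seed=seed)


def _study_flags(
    n_studies: int,
    shifts: Mapping[str, Mapping[str, float]] | None,
    n_per_group: int,
    cv: float,
    seed: int,
    alpha: float = 0.05,
) -> tuple[dict[str, int], dict[str, int]]:
    rng = np.random.default_rng(seed)
    family = {p: 0 for p in ("e0", "a_over_c", "beta", "de", "b")}
    agnp_vs_control = {p: 0 for p in family}
    for _ in range(n_studies):
        table = simulate_fit_table(shifts=shifts, n_per_group=n_per_group, cv=cv, rng=rng)
        report = compare_parameters(table, alpha=alpha)
        for param, entry in report.items():
            if any(pw.significant for pw in entry["pairwise"]):
                family[param] += 1
            for pw in entry["pairwise"]:
                if set(pw.label.split(" vs ")) == {"AgNP", "HBSS"} and pw.significant:
                    agnp_vs_control[param] += 1
    return family, agnp_vs_control


def family_rejection_rates(
    n_studies: int = 200, n_per_group: int = 5, cv: float = 0.15, seed: int = 0
) -> dict[str, float]:
    """Null-template type-I calibration.

    Simulates studies with no treatment effect and returns, per parameter
    family, the fraction of studies in which any Holm-Sidak-adjusted
    treatment pair was flagged (family-wise rejection frequency).
    """
    family, _ = _study_flags(n_studies, None, n_per_group, cv, seed)
    return {p: k / n_studies for p, k in family.items()}


def agnp_detection_rates(
    n_studies: int = 200, n_per_group: int = 6, cv: float = 0.1, seed: int = 0
) -> dict[str, float]:
    """Power of the AgNP-vs-control comparison under the day-7 effect template."""
    _, agnp = _study_flags(n_studies, DAY7_AGNP_SHIFTS, n_per_group, cv, seed)
    return {p: k / n_studies for p, k in agnp.items()}


def bootstrap_coverage(
    n_replicates: int = 500,
    n_boot: int = 300,
    noise_frac: float = 0.02,
    seed: int = 0,
    base: MechParams = DEFAULT_BASE_PARAMS,
) -> float:
    """Fraction of 95% bootstrap intervals for a/c that cover the truth.

    Noise sd is ``noise_frac`` of the RMS resistance signal (2% by default),
    freshly drawn per replicate.
    """
    freqs = np.asarray(DEFAULT_FREQUENCIES)
    clean = predict_spectra(base, freqs)
    sd_r = noise_frac * float(np.sqrt(np.mean(np.asarray(clean.rl) ** 2)))
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        noisy = RESpectra(
            freqs=freqs, rl=clean.rl + rng.normal(0.0, sd_r, freqs.size), el=clean.el
        )
        lo, hi = bootstrap_ci(noisy, n_boot=n_boot, rng=rng, curves=("resistance",))["a_over_c"]
        if lo < base.a_over_c < hi:
            covered += 1
    return covered / n_replicates
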