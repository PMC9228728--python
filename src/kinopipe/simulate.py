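"""Synthetic spot-level kinome datasets with known ground truth.

No raw scans are publicly deposited for this class of experiment, so the
generator produces arrays with the statistical structure the analysis
pipeline assumes: a log-normal multiplicative intensity core (which induces
the mean-variance coupling that variance-stabilizing normalization removes),
additive Gaussian background, per-array scale effects, planted log-scale
treatment effects with random sign, and a planted fraction of peptides whose
technical replicates have inflated variance (the targets of the chi-squared
consistency filter).

Generative model, per array k (one per biological subject), peptide p,
technical replicate i::

    raw = background_offset + exp(mu_p + alpha_k + effect_{p,g} + eps_pki) + eta_pki

with ``eps ~ Normal(0, sigma_m^2 * kappa^[p inconsistent])`` on the log scale
and ``eta ~ Normal(0, sigma_a^2)`` additive background noise, truncated so
raw intensities stay nonnegative.  PBS groups carry effect 0 by construction
(control semantics).  Generation is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ArrayDesign, SPOT_COLUMNS, default_peptide_catalogue

__all__ = ["SimulationConfig", "default_groups", "simulate", "truth_recovery_report"]


def default_groups() -> tuple[tuple[str, str, int], ...]:
    """The study layout: 3 treatments x 2 tissues x 5 biological subjects."""
    return tuple(
        (treatment, tissue, 5)
        for tissue in ("MUSCLE", "LYMPH_NODE")
        for treatment in ("PBS", "PCEP", "ALUM")
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-array generator.

    Defaults emulate the study design (282 peptides x 9 technical replicates,
    3 treatments x 2 tissues x 5 subjects) with raw intensities spanning
    roughly 2.5 decades.  ``effect_log_mean`` is the planted log-scale shift
    for differential peptides (random sign per peptide and contrast);
    ``kappa`` multiplies the technical-replicate *variance* of planted
    inconsistent peptides.
    """

    design: ArrayDesign = field(
        default_factory=lambda: ArrayDesign(default_peptide_catalogue(282), 9)
    )
    groups: tuple[tuple[str, str, int], ...] = field(default_factory=default_groups)
    baseline_log_mean: float = 6.5
    baseline_log_sd: float = 1.4
    array_effect_sd: float = 0.2
    mult_noise_sd: float = 0.25
    add_noise_sd: float = 8.0
    background_offset: float = 50.0
    frac_differential: float = 0.2
    effect_log_mean: float = 1.0
    frac_inconsistent: float = 0.1
    kappa: float = 25.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one (treatment, tissue, n_subjects) group required")
        for sd_name in ("baseline_log_sd", "array_effect_sd", "mult_noise_sd", "add_noise_sd"):
            if getattr(self, sd_name) <= 0:
                raise ValueError(f"{sd_name} must be > 0")
        for frac_name in ("frac_differential", "frac_inconsistent"):
            if not 0.0 <= getattr(self, frac_name) <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1]")
        if self.kappa <= 1.0:
            raise ValueError("kappa must be > 1")
        if self.background_offset < 0:
            raise ValueError("background_offset must be >= 0")
        for treatment, tissue, n in self.groups:
            if n < 2:
                raise ValueError(f"group ({treatment}, {tissue}): n_subjects must be >= 2")


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one dataset.

    Returns ``(spots, truth)``: a long-form spot table with
    :data:`kinopipe.io.SPOT_COLUMNS`, and a truth table with one row per
    (peptide, treatment, tissue) carrying ``true_effect``, ``is_differential``
    and ``is_inconsistent``.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    P, R = design.n_peptides, design.n_tech_replicates
    peptide_ids = np.asarray(design.peptide_ids)

    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=P)

    # planted structure: one global inconsistent set, per-contrast effects
    inconsistent = rng.random(P) < config.frac_inconsistent

    effects: dict[tuple[str, str], np.ndarray] = {}
    for treatment, tissue, _ in config.groups:
        key = (treatment, tissue)
        if treatment == "PBS":
            effects[key] = np.zeros(P)
        else:
            differential = rng.random(P) < config.frac_differential
            signs = rng.choice([-1.0, 1.0], size=P)  # Rademacher
            effects[key] = np.where(differential, signs * config.effect_log_mean, 0.0)

    spot_frames = []
    for treatment, tissue, n_subjects in config.groups:
        effect = effects[(treatment, tissue)]
        for subj in range(1, n_subjects + 1):
            array_id = f"{tissue}_{treatment}_s{subj}"
            alpha = rng.normal(0.0, config.array_effect_sd)
            log_level = mu + alpha + effect  # (P,)
            sd = np.where(
                inconsistent,
                config.mult_noise_sd * np.sqrt(config.kappa),
                config.mult_noise_sd,
            )
            eps = rng.normal(0.0, 1.0, size=(P, R)) * sd[:, None]
            eta = rng.normal(0.0, config.add_noise_sd, size=(P, R))
            raw = config.background_offset + np.exp(log_level[:, None] + eps) + eta
            np.maximum(raw, 0.0, out=raw)  # truncate, not resample
            spot_frames.append(
                pd.DataFrame(
                    {
                        "array_id": array_id,
                        "treatment": treatment,
                        "tissue": tissue,
                        "subject_id": f"{tissue}_{treatment}_{subj}",
                        "peptide_id": np.repeat(peptide_ids, R),
                        "replicate_index": np.tile(np.arange(1, R + 1), P),
                        "raw_intensity": raw.ravel(),
                    }
                )
            )
    spots = pd.concat(spot_frames, ignore_index=True)[list(SPOT_COLUMNS)]

    truth_rows = []
    for treatment, tissue, _ in config.groups:
        effect = effects[(treatment, tissue)]
        truth_rows.append(
            pd.DataFrame(
                {
                    "peptide_id": peptide_ids,
                    "treatment": treatment,
                    "tissue": tissue,
                    "true_effect": effect,
                    "is_differential": effect != 0.0,
                    "is_inconsistent": inconsistent,
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return spots, truth


def truth_recovery_report(truth: pd.DataFrame, called_peptides, treatment: str,
                          tissue: str) -> dict[str, float]:
    """Confusion-matrix rates of a differential call set against the planted
    truth for one (treatment, tissue) contrast.

    ``called_peptides`` is any iterable of peptide ids the pipeline called
    differential.  Returns sensitivity, specificity and the observed false
    discovery rate (0 when nothing is called).
    """
    sub = truth[(truth["treatment"] == treatment) & (truth["tissue"] == tissue)]
    if sub.empty:
        raise ValueError(f"no truth rows for contrast ({treatment}, {tissue})")
    universe = set(sub["peptide_id"])
    called = set(called_peptides)
    stray = called - universe
    if stray:
        raise ValueError(f"called peptides outside the truth universe: {sorted(stray)[:5]}")
    positives = set(sub.loc[sub["is_differential"], "peptide_id"])
    tp = len(called & positives)
    fp = len(called - positives)
    fn = len(positives - called)
    tn = len(universe) - tp - fp - fn
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "fdr": fp / (tp + fp) if (tp + fp) else 0.0,
        "n_called": float(len(called)),
        "n_true": float(len(positives)),
    }
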