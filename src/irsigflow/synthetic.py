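"""Synthetic cohort generator with known ground truth.

Emulates the data structure of an HIV-and-aging cytometry study: four subject
groups (uninfected/HIV x younger/older), per-subject event matrices over seven
lineage and five inhibitory-receptor (IR) channels, per-batch background
controls stained without the five IR antibodies (FM5), a plasma analyte panel,
and culture-supernatant analytes whose per-cell secretion depends on the
subject's TIGIT+ fraction with group-specific slopes.

Generative model, per cell:

* a cell subset (gamma-delta T, CD4 T, CD8 T, NK, other) is drawn from the
  group's mixture weights; lineage channels are Gaussian around subset-specific
  means (arcsinh units);
* each IR has a per-cell positivity log-odds: a baseline, plus HIV and age
  shifts and a subject-level random intercept on gamma-delta cells, plus a
  shared per-cell latent activation scalar scaled by a per-IR loading. The
  latent scalar induces positive IR co-expression, without which multi-IR
  fractions and combination trajectories would be degenerate;
* bimodal IRs (PD-1, TIGIT, CD160) draw fluorescence from a positive or a
  negative Gaussian according to that log-odds; non-bimodal IRs (TIM-3, LAG-3)
  are a single Gaussian whose mean shifts continuously with the same log-odds.

Events are generated directly in arcsinh space; a raw-space export is available
through :func:`irsigflow.events.inverse_arcsinh_transform`. All generators are
seed-deterministic.

These distributional choices are stand-ins: no public per-event data accompany
the study design being emulated, so every generative parameter here is a
configurable assumption, not an estimate.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .events import (
    DEFAULT_COFACTOR,
    IR_CHANNELS,
    LINEAGE_CHANNELS,
    VIABILITY_CHANNEL,
    EventMatrix,
    default_channel_roles,
)

GROUPS = ("uninfected_young", "uninfected_old", "hiv_young", "hiv_old")
SUBSETS = ("gdT", "CD4T", "CD8T", "NK", "other")

PLASMA_ANALYTES = (
    "sCD14", "sCD163", "A2M", "fibrinogen", "SAP", "adipsin", "vWF", "D-dimer",
    "CRP", "CXCL4", "L-selectin", "IL-6", "IL-1b", "TNF-a", "haptoglobin", "SAA",
)

SUPERNATANT_ANALYTES = (
    "sCD137", "GranzymeA", "GranzymeB", "perforin", "MIP-1b", "CCL20",
    "TNF-a", "IFN-g", "IL-6", "GM-CSF", "IL-8",
    # rarely-secreted analytes, mostly below detection
    "IL-4", "IL-10", "IL-17A",
)
RARE_ANALYTES = ("IL-4", "IL-10", "IL-17A")


class ConfigError(ValueError):
    """Raised when a synthetic configuration field fails validation."""


def _default_subset_weights() -> dict[str, dict[str, float]]:
    # gamma-delta T held above the 5% cluster-size floor so the population is
    # discoverable by size-thresholded clustering, as in the emulated design
    w = {"gdT": 0.08, "CD4T": 0.40, "CD8T": 0.25, "NK": 0.17, "other": 0.10}
    return {g: dict(w) for g in GROUPS}


def _default_lineage_means() -> dict[str, dict[str, float]]:
    # arcsinh units; ~0.3 = negative, ~4 = bright
    return {
        "gdT":   {"CD3": 4.0, "CD4": 0.3, "CD8": 0.6, "gdTCR": 4.0, "CD127": 0.5, "CD16": 1.5, "CD56": 1.5},
        "CD4T":  {"CD3": 4.0, "CD4": 4.0, "CD8": 0.3, "gdTCR": 0.3, "CD127": 3.0, "CD16": 0.3, "CD56": 0.3},
        "CD8T":  {"CD3": 4.0, "CD4": 0.3, "CD8": 4.0, "gdTCR": 0.3, "CD127": 2.0, "CD16": 0.3, "CD56": 0.3},
        "NK":    {"CD3": 0.3, "CD4": 0.3, "CD8": 1.0, "gdTCR": 0.3, "CD127": 0.5, "CD16": 3.5, "CD56": 3.5},
        "other": {"CD3": 0.3, "CD4": 1.0, "CD8": 0.3, "gdTCR": 0.3, "CD127": 0.8, "CD16": 0.6, "CD56": 0.3},
    }


@dataclasses.dataclass
class SyntheticConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    Group sizes default to 21/21/22/28 (uninfected younger/older, HIV younger/
    older). IR effects are on the log-odds (logit) scale of per-cell positivity
    on gamma-delta T cells; plasma effects are on the log-concentration scale;
    supernatant secretion is a per-group linear model in the subject's TIGIT+
    fraction, in pg per cell.
    """

    group_sizes: tuple[int, int, int, int] = (21, 21, 22, 28)
    events_per_subject: int = 10_000
    n_batches: int = 11
    seed: int = 0

    subset_weights: dict = dataclasses.field(default_factory=_default_subset_weights)
    lineage_means: dict = dataclasses.field(default_factory=_default_lineage_means)
    lineage_sd: float = 0.4

    # log-odds of IR positivity on gamma-delta T cells
    ir_base_logit: dict = dataclasses.field(default_factory=lambda: {
        "PD-1": -1.4, "TIGIT": -0.8, "TIM-3": -1.5, "CD160": -1.0, "LAG-3": -2.2,
    })
    ir_hiv_effect: dict = dataclasses.field(default_factory=lambda: {
        "PD-1": -0.3, "TIGIT": 1.2, "TIM-3": 0.7, "CD160": 0.4, "LAG-3": 0.0,
    })
    ir_age_effect: dict = dataclasses.field(default_factory=lambda: {
        "PD-1": 0.0, "TIGIT": 0.6, "TIM-3": 0.0, "CD160": 0.2, "LAG-3": 0.0,
    })
    subject_sd: float = 0.3
    coexpression_loading: dict = dataclasses.field(default_factory=lambda: {
        "PD-1": 0.8, "TIGIT": 0.8, "TIM-3": 0.5, "CD160": 0.6, "LAG-3": 0.5,
    })
    smooth_ir_set: tuple[str, ...] = ("TIM-3", "LAG-3")
    #: IR baseline shift on non-gamma-delta cells (no group effects there)
    nongd_ir_offset: float = -1.5

    pos_intensity: tuple[float, float] = (2.5, 0.45)
    neg_intensity: tuple[float, float] = (0.15, 0.35)
    #: arcsinh-units shift of a smooth IR per unit positivity probability
    smooth_gain: float = 1.6
    viability_intensity: tuple[float, float] = (0.3, 0.15)

    # plasma panel, log-concentration scale
    plasma_base: dict = dataclasses.field(default_factory=lambda: {a: 3.0 for a in PLASMA_ANALYTES})
    plasma_hiv_effect: dict = dataclasses.field(default_factory=lambda: {
        **{a: 0.0 for a in PLASMA_ANALYTES},
        "sCD14": 0.4, "A2M": 0.3, "fibrinogen": 0.3, "SAP": 0.3, "adipsin": 0.3, "vWF": 0.4,
    })
    plasma_age_effect: dict = dataclasses.field(default_factory=lambda: {
        **{a: 0.0 for a in PLASMA_ANALYTES},
        "D-dimer": 0.4, "CRP": 0.4, "fibrinogen": 0.2, "SAP": 0.2, "adipsin": 0.2, "vWF": 0.2,
    })
    plasma_tigit_coupling: dict = dataclasses.field(default_factory=lambda: {
        **{a: 0.0 for a in PLASMA_ANALYTES},
        "IL-6": 1.0, "TNF-a": 0.8, "IL-1b": 0.6, "D-dimer": 0.6, "CRP": 0.6,
        "sCD14": 0.5, "fibrinogen": 0.4, "vWF": 0.4, "L-selectin": -0.4,
    })
    plasma_noise_sd: float = 0.35

    # supernatant secretion: per-cell pg = intercept + slope_g * tigit_fraction
    secretion_intercept: dict = dataclasses.field(default_factory=lambda: {
        **{a: 1e-3 for a in SUPERNATANT_ANALYTES},
        **{a: 2e-6 for a in RARE_ANALYTES},
    })
    secretion_slope: dict = dataclasses.field(default_factory=lambda: {
        "uninfected_young": {**{a: 0.0 for a in SUPERNATANT_ANALYTES}, "MIP-1b": -1.5e-3},
        "uninfected_old": {**{a: 0.0 for a in SUPERNATANT_ANALYTES}, "MIP-1b": -1.5e-3},
        "hiv_young": {**{a: 4e-3 for a in SUPERNATANT_ANALYTES}, **{a: 0.0 for a in RARE_ANALYTES}},
        "hiv_old": {**{a: 4e-3 for a in SUPERNATANT_ANALYTES}, **{a: 0.0 for a in RARE_ANALYTES}},
    })
    secretion_noise_sd: float = 5e-4
    cells_per_well_range: tuple[int, int] = (2_000, 26_000)
    #: pg per well below which an analyte is recorded as undetected
    detection_limit: float = 1.0

    cofactor: float = DEFAULT_COFACTOR

    def validate(self) -> None:
        if len(self.group_sizes) != 4:
            raise ConfigError("group_sizes must have exactly 4 entries")
        if any(int(n) != n or n < 0 for n in self.group_sizes):
            raise ConfigError("group_sizes must be non-negative integers")
        if self.events_per_subject <= 0:
            raise ConfigError("events_per_subject must be positive")
        if self.n_batches <= 0:
            raise ConfigError("n_batches must be positive")
        for g in GROUPS:
            w = self.subset_weights.get(g)
            if w is None or set(w) != set(SUBSETS):
                raise ConfigError(f"subset_weights[{g!r}] must cover subsets {SUBSETS}")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ConfigError(f"subset_weights[{g!r}] must sum to 1 within 1e-9")
            if any(v < 0 for v in w.values()):
                raise ConfigError(f"subset_weights[{g!r}] must be non-negative")
        for name, val in [("lineage_sd", self.lineage_sd),
                          ("subject_sd", self.subject_sd),
                          ("pos_intensity sd", self.pos_intensity[1]),
                          ("neg_intensity sd", self.neg_intensity[1]),
                          ("plasma_noise_sd", self.plasma_noise_sd),
                          ("secretion_noise_sd", self.secretion_noise_sd),
                          ("viability sd", self.viability_intensity[1])]:
            if not val > 0:
                raise ConfigError(f"{name} must be > 0")
        for ir in IR_CHANNELS:
            for field in ("ir_base_logit", "ir_hiv_effect", "ir_age_effect", "coexpression_loading"):
                if ir not in getattr(self, field):
                    raise ConfigError(f"{field} missing entry for {ir!r}")
        lo, hi = self.cells_per_well_range
        if not (0 < lo <= hi):
            raise ConfigError("cells_per_well_range must satisfy 0 < lo <= hi")
        if not self.cofactor > 0:
            raise ConfigError("cofactor must be > 0")


@dataclasses.dataclass
class AnalytePanel:
    """Subjects x analytes concentration table with detection bookkeeping."""

    values: pd.DataFrame
    units: str
    detection_mask: pd.DataFrame
    cells_per_well: pd.Series | None = None
    per_cell_normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ConfigError("analyte concentrations must be >= 0")
        if self.per_cell_normalized and self.cells_per_well is None:
            raise ConfigError("per_cell_normalized requires cells_per_well")
        if self.detection_mask.shape != self.values.shape:
            raise ConfigError("detection_mask must match values shape")

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)


def _group_label(hiv: int, age_group: str) -> str:
    return ("hiv_" if hiv else "uninfected_") + ("old" if age_group == "old" else "young")


def generate_design(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort design table: subject_id, hiv, age_group, batch.

    Batches are assigned cyclically over a randomly permuted subject order so
    every batch mixes the four groups, mirroring run-balanced staining batches.
    """
    rows = []
    specs = [("uninfected", "young"), ("uninfected", "old"), ("hiv", "young"), ("hiv", "old")]
    i = 0
    for (status, age), n in zip(specs, config.group_sizes):
        for _ in range(int(n)):
            i += 1
            rows.append({
                "subject_id": f"S{i:03d}",
                "hiv": int(status == "hiv"),
                "age_group": age,
            })
    design = pd.DataFrame(rows)
    order = rng.permutation(len(design))
    batch = np.empty(len(design), dtype=int)
    batch[order] = np.arange(len(design)) % config.n_batches + 1
    design["batch"] = batch
    return design


def _subject_events(
    config: SyntheticConfig,
    group: str,
    subject_intercepts: Mapping[str, float],
    rng: np.random.Generator,
    n_events: int,
    fm5: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event values and hidden per-event metadata for one sample."""
    weights = config.subset_weights[group]
    subset_idx = rng.choice(len(SUBSETS), size=n_events, p=[weights[s] for s in SUBSETS])
    subsets = np.array(SUBSETS)[subset_idx]

    cols: dict[str, np.ndarray] = {}
    for ch in LINEAGE_CHANNELS:
        means = np.array([config.lineage_means[s][ch] for s in SUBSETS])[subset_idx]
        cols[ch] = rng.normal(means, config.lineage_sd)

    latent = rng.standard_normal(n_events)
    is_gd = subsets == "gdT"
    hiv = group.startswith("hiv_")
    old = group.endswith("_old")
    neg_mu, neg_sd = config.neg_intensity
    pos_mu, pos_sd = config.pos_intensity

    truth_pos: dict[str, np.ndarray] = {}
    for ir in IR_CHANNELS:
        if fm5:
            # control stained without the five IR antibodies: background only
            cols[ir] = rng.normal(neg_mu, neg_sd, size=n_events)
            truth_pos[ir] = np.zeros(n_events, dtype=bool)
            continue
        logit_cell = (
            config.ir_base_logit[ir]
            + config.coexpression_loading[ir] * latent
            + np.where(
                is_gd,
                hiv * config.ir_hiv_effect[ir]
                + old * config.ir_age_effect[ir]
                + subject_intercepts[ir],
                config.nongd_ir_offset,
            )
        )
        p = expit(logit_cell)
        if ir in config.smooth_ir_set:
            # unimodal continuous shift rather than a positive component
            cols[ir] = neg_mu + config.smooth_gain * p + rng.normal(0.0, neg_sd, size=n_events)
            truth_pos[ir] = p > 0.5
        else:
            pos = rng.random(n_events) < p
            vals = rng.normal(neg_mu, neg_sd, size=n_events)
            vals[pos] = rng.normal(pos_mu, pos_sd, size=int(pos.sum()))
            cols[ir] = vals
            truth_pos[ir] = pos

    v_mu, v_sd = config.viability_intensity
    cols[VIABILITY_CHANNEL] = rng.normal(v_mu, v_sd, size=n_events)

    values = pd.DataFrame(cols)
    meta = pd.DataFrame({"subset": subsets, **{f"pos_{ir}": truth_pos[ir] for ir in IR_CHANNELS}})
    return values, meta


def expected_gd_positivity(config: SyntheticConfig, ir: str, group: str,
                           subject_intercept: float = 0.0) -> float:
    """Per-subject expected IR+ fraction on gamma-delta cells.

    Integrates the per-cell latent activation scalar out of the inverse-logit
    using the logistic-normal mean approximation
    ``E[expit(l + s Z)] ~= expit(l / sqrt(1 + pi^2 s^2 / 8))``.
    """
    hiv = group.startswith("hiv_")
    old = group.endswith("_old")
    l = (config.ir_base_logit[ir] + hiv * config.ir_hiv_effect[ir]
         + old * config.ir_age_effect[ir] + subject_intercept)
    s = config.coexpression_loading[ir]
    return float(expit(l / np.sqrt(1.0 + np.pi ** 2 * s ** 2 / 8.0)))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, list[EventMatrix], list[EventMatrix], AnalytePanel]:
    """Generate the full synthetic study.

    Returns ``(design, events, fm5_controls, plasma)``:

    * ``design`` — cohort table with ``truth_*`` columns recording each
      subject's generative TIGIT+ gamma-delta fraction (ground truth for
      downstream checks; the analysis never reads them);
    * ``events`` — one arcsinh-space :class:`EventMatrix` per subject, with the
      hidden cell-subset labels in ``meta``;
    * ``fm5_controls`` — one background control per batch, IR channels drawn
      from the negative component only;
    * ``plasma`` — 16-analyte panel with HIV/age shifts and TIGIT coupling on
      the log scale.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_design, rng_subjects, rng_fm5, rng_plasma = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]
    design = generate_design(config, rng_design)
    roles = default_channel_roles()

    events: list[EventMatrix] = []
    truth_tigit = []
    for _, row in design.iterrows():
        group = _group_label(row.hiv, row.age_group)
        intercepts = {ir: rng_subjects.normal(0.0, config.subject_sd) for ir in IR_CHANNELS}
        values, meta = _subject_events(
            config, group, intercepts, rng_subjects, config.events_per_subject
        )
        events.append(EventMatrix(row.subject_id, values, roles, "arcsinh", config.cofactor, meta))
        truth_tigit.append(expected_gd_positivity(config, "TIGIT", group, intercepts["TIGIT"]))
    design = design.assign(truth_tigit_fraction=truth_tigit)

    fm5_controls = []
    for b in range(1, config.n_batches + 1):
        # FM5 pools 5% of each sample in the batch; use cohort-average weights
        values, meta = _subject_events(
            config, "uninfected_young", {ir: 0.0 for ir in IR_CHANNELS},
            rng_fm5, config.events_per_subject, fm5=True,
        )
        fm5_controls.append(
            EventMatrix(f"FM5_batch{b}", values, roles, "arcsinh", config.cofactor, meta)
        )

    plasma = _generate_plasma(design, config, rng_plasma)
    return design, events, fm5_controls, plasma


def _generate_plasma(design: pd.DataFrame, config: SyntheticConfig,
                     rng: np.random.Generator) -> AnalytePanel:
    hiv = design["hiv"].to_numpy()
    old = (design["age_group"] == "old").to_numpy().astype(int)
    tigit = design["truth_tigit_fraction"].to_numpy()
    cols = {}
    for a in PLASMA_ANALYTES:
        log_c = (config.plasma_base[a]
                 + config.plasma_hiv_effect[a] * hiv
                 + config.plasma_age_effect[a] * old
                 + config.plasma_tigit_coupling[a] * tigit
                 + rng.normal(0.0, config.plasma_noise_sd, size=len(design)))
        cols[a] = np.exp(log_c)
    values = pd.DataFrame(cols, index=design["subject_id"].to_numpy())
    mask = pd.DataFrame(True, index=values.index, columns=values.columns)
    return AnalytePanel(values, units="pg/ml", detection_mask=mask)


def generate_supernatant(
    design: pd.DataFrame,
    tigit_fraction: pd.Series,
    config: SyntheticConfig,
    seed: int | None = None,
) -> AnalytePanel:
    """Culture-supernatant analyte panel (pg per well).

    Per-cell secretion is ``intercept + slope_group * tigit_fraction`` plus
    Gaussian noise truncated at zero; well totals multiply by a cultured cell
    count drawn uniformly from ``cells_per_well_range``.
    """
    config.validate()
    subjects = design["subject_id"].to_numpy()
    if set(tigit_fraction.index) != set(subjects):
        raise ConfigError("tigit_fraction subjects do not match the design")
    frac = tigit_fraction.reindex(subjects).to_numpy(dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ConfigError("tigit_fraction must lie in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed).spawn(1)[0]
    )
    groups = [_group_label(h, a) for h, a in zip(design["hiv"], design["age_group"])]
    lo, hi = config.cells_per_well_range
    cells = pd.Series(rng.integers(lo, hi + 1, size=len(subjects)), index=subjects)
    cols = {}
    for a in SUPERNATANT_ANALYTES:
        slopes = np.array([config.secretion_slope[g][a] for g in groups])
        per_cell = (config.secretion_intercept[a] + slopes * frac
                    + rng.normal(0.0, config.secretion_noise_sd, size=len(subjects)))
        per_cell = np.clip(per_cell, 0.0, None)
        cols[a] = per_cell * cells.to_numpy()
    values = pd.DataFrame(cols, index=subjects)
    mask = values >= config.detection_limit
    return AnalytePanel(values, units="pg/well", detection_mask=mask, cells_per_well=cells)


def generate_null_abundances(
    n_subjects: int,
    n_subsets: int,
    seed: int = 0,
    concentration: float = 5.0,
) -> pd.DataFrame:
    """Exchangeable null abundance table for permutation-threshold calibration.

    Each subject's abundances over ``n_subsets`` categories are drawn from a
    symmetric Dirichlet, so the within-subject permutation null holds exactly
    and no covariate carries signal.
    """
    if n_subsets < 2:
        raise ConfigError("n_subsets must be >= 2")
    if n_subjects < 4:
        raise ConfigError("n_subjects must be >= 4 to fit the two-term model")
    if not concentration > 0:
        raise ConfigError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    vals = rng.dirichlet([concentration] * n_subsets, size=n_subjects)
    return pd.DataFrame(
        vals,
        index=[f"S{i + 1:03d}" for i in range(n_subjects)],
        columns=[f"subset_{j + 1}" for j in range(n_subsets)],
    )
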