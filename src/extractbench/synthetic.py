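"""Synthetic kit-style measurement tables with known ground truth.

The generator emulates the design of a broad-coverage quantitative
metabolomics kit study: a fixed ~630-metabolite panel spanning 14
small-molecule (LC-MS/MS) and 9 lipid (FIA-MS/MS) classes, several sample
matrices (organism × tissue), a set of extraction protocols and triplicate
measurements per (matrix, protocol).

Concentrations follow a lognormal model on the log2 scale::

    log2 conc = baseline(metabolite) + effect(protocol, class) + noise

with noise ~ N(0, sigma) and sigma derived from the target replicate CV via
the exact lognormal relation sigma_ln = sqrt(ln(1 + (cv/100)^2)), converted
to log2 by dividing by ln 2, so the population CV of the generated
replicates equals the configured CV exactly (not only for small CVs).

Censoring mimics instrument detection limits: each metabolite receives one
constant LOD, placed so that the configured fraction of its marginal
concentration distribution falls below it (the threshold is solved from the
analytic normal-mixture CDF of the log2 marginal, so the expected
below-LOD fraction equals ``lod_quantile`` exactly).  Cells below LOD are
flagged ``below_lod``; the LOQ is placed the same way at ``loq_quantile``
(so below-LOD and below-LOQ cell fractions are controlled directly) and
cells between the two are ``below_loq``; both keep their numeric value, as
kit software exports do.  Independent missing-at-random masking removes cells entirely.

Randomness is fully reproducible: one NumPy Philox-family substream per
metabolite, derived from the table seed and a stable 64-bit hash of the
metabolite name, consumed in a canonical (sorted) sample order — the draw
for a metabolite does not depend on panel insertion order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import binom

from .detectability import DetectionRule
from .model import (
    AcquisitionMode,
    ConfigError,
    MatrixKey,
    MeasurementTable,
    Metabolite,
    MetabolitePanel,
    QuantStatus,
    SampleKey,
)

__all__ = [
    "DEFAULT_PANEL_SPEC",
    "DEFAULT_PROTOCOLS",
    "DEFAULT_MATRICES",
    "SCENARIOS",
    "SyntheticConfig",
    "GroundTruth",
    "default_panel",
    "cv_to_sigma_log2",
    "generate",
    "plant_scenario",
]

#: Extraction protocols of the emulated study design, ordered monophasic →
#: biphasic by handling complexity.
DEFAULT_PROTOCOLS: tuple[str, ...] = (
    "100IPA",
    "IPA/ACN/H2O",
    "MeOH/ACN/H2O+FA",
    "MeOH/CHCl3/H2O",
    "75EtOH/MTBE",
    "MeOH/MTBE",
    "2xMeOH/MTBE",
)

DEFAULT_MATRICES: tuple[MatrixKey, ...] = (
    ("drosophila", "whole"),
    ("mouse", "kidney"),
    ("mouse", "liver"),
    ("zebrafish", "liver"),
)

#: class → (metabolite count, acquisition mode, name prefix).  14 LC classes
#: (107 small molecules) + 9 FIA classes (523 lipids) = 630 over 23 classes,
#: mirroring a broad-coverage kit panel.
DEFAULT_PANEL_SPEC: dict[str, tuple[int, str, str]] = {
    "alkaloids": (1, "LC", "ALK"),
    "amine oxides": (1, "LC", "AOX"),
    "amino acids": (20, "LC", "AA"),
    "amino acid related": (30, "LC", "AAR"),
    "bile acids": (14, "LC", "BA"),
    "biogenic amines": (9, "LC", "BAM"),
    "carbohydrates": (1, "LC", "SUG"),
    "carboxylic acids": (7, "LC", "CA"),
    "cresols": (1, "LC", "CRE"),
    "fatty acids": (12, "LC", "FA"),
    "hormones": (4, "LC", "HOR"),
    "indole derivatives": (4, "LC", "IND"),
    "nucleobase related": (2, "LC", "NUC"),
    "vitamins & cofactors": (1, "LC", "VIT"),
    "acylcarnitines": (40, "FIA", "AC"),
    "lysophosphatidylcholines": (14, "FIA", "LPC"),
    "phosphatidylcholines": (76, "FIA", "PC"),
    "sphingomyelins": (15, "FIA", "SM"),
    "ceramides": (36, "FIA", "CER"),
    "glycosylceramides": (34, "FIA", "HEXCER"),
    "diacylglycerols": (44, "FIA", "DG"),
    "triacylglycerols": (242, "FIA", "TG"),
    "cholesteryl esters": (22, "FIA", "CE"),
}

SCENARIOS = ("global_null", "one_winner", "two_tied_winners", "class_specific_winner")


def default_panel(
    panel_spec: Mapping[str, tuple[int, str, str]] | None = None,
) -> MetabolitePanel:
    """Build the demonstration panel from a class → (count, mode, prefix) spec."""
    spec = DEFAULT_PANEL_SPEC if panel_spec is None else panel_spec
    mets: list[Metabolite] = []
    for cls, (count, mode, prefix) in spec.items():
        for i in range(1, count + 1):
            mets.append(Metabolite(f"{prefix}{i:03d}", cls, AcquisitionMode(mode)))
    return MetabolitePanel(tuple(mets))


def cv_to_sigma_log2(cv_percent: float) -> float:
    """Exact lognormal noise SD (log2 scale) for a target replicate CV%."""
    cv = cv_percent / 100.0
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of one synthetic kit table.

    ``protocol_effects`` maps (protocol, compound class) → log2 shift of
    that class's mean under that protocol; unlisted pairs shift by 0.
    ``replicate_cv_percent`` is a single target CV or a class → CV mapping.
    ``lod_quantile`` is the expected below-LOD cell fraction per metabolite
    (0 disables censoring); ``loq_quantile`` the expected fraction below the
    LOQ (below-LOD cells included, so it must be >= lod_quantile);
    ``missing_rate`` the independent missing-at-random cell probability.
    """

    panel_spec: Mapping[str, tuple[int, str, str]] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_SPEC)
    )
    matrices: tuple[MatrixKey, ...] = DEFAULT_MATRICES
    protocols: tuple[str, ...] = DEFAULT_PROTOCOLS
    replicates: int = 3
    baseline_log2_mean_range: tuple[float, float] = (-2.0, 12.0)
    protocol_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    replicate_cv_percent: float | Mapping[str, float] = 15.0
    lod_quantile: float = 0.1
    loq_quantile: float = 0.2
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ConfigError(f"replicates must be >= 2, got {self.replicates}")
        if not (0.0 <= self.lod_quantile < 1.0):
            raise ConfigError(f"lod_quantile must be in [0, 1), got {self.lod_quantile}")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ConfigError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if not (self.lod_quantile <= self.loq_quantile < 1.0):
            raise ConfigError(
                "loq_quantile must lie in [lod_quantile, 1), got "
                f"{self.loq_quantile}"
            )
        for key, eff in self.protocol_effects.items():
            if not math.isfinite(eff):
                raise ConfigError(f"non-finite protocol effect for {key}")
            prot, cls = key
            if prot not in self.protocols:
                raise ConfigError(f"effect for unknown protocol {prot!r}")
            if cls not in self.panel_spec:
                raise ConfigError(f"effect for unknown class {cls!r}")
        lo, hi = self.baseline_log2_mean_range
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ConfigError("baseline_log2_mean_range must be a finite interval")

    def sigma_log2(self, compound_class: str) -> float:
        cv = self.replicate_cv_percent
        if isinstance(cv, Mapping):
            cv = cv.get(compound_class, 15.0)
        if cv < 0:
            raise ConfigError(f"negative replicate CV {cv}")
        return cv_to_sigma_log2(float(cv))


@dataclass
class GroundTruth:
    """What the generator planted, for bookkeeping in tests and recovery checks."""

    panel: MetabolitePanel
    baselines: pd.Series                 # metabolite → true baseline (log2)
    effects: pd.DataFrame                # metabolite × protocol log2 shifts
    lod: pd.Series                       # metabolite → LOD (linear scale)
    p_above_lod: pd.DataFrame            # metabolite × protocol P(cell > LOD)
    expected_detectable: pd.DataFrame    # metabolite × protocol bool
    planted_winner: dict[str, str | None]  # class → protocol or None

    def to_json_dict(self) -> dict:
        return {
            "planted_winner": self.planted_winner,
            "baseline_log2": {k: float(v) for k, v in self.baselines.items()},
            "lod": {k: float(v) for k, v in self.lod.items()},
            "effects_log2": {
                met: {
                    p: float(e)
                    for p, e in row.items()
                    if e != 0.0
                }
                for met, row in self.effects.iterrows()
            },
        }


def _met_substream(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.blake2b(name.encode("utf-8"), digest_size=8).digest()
    key = int.from_bytes(digest, "big")
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def _mixture_quantile(offsets: np.ndarray, sigma: float, q: float) -> float:
    """q-quantile of an equal-weight normal mixture N(offset_i, sigma)."""
    if q <= 0.0:
        return -math.inf
    if sigma == 0.0:
        return float(np.quantile(offsets, q, method="inverted_cdf"))
    lo = float(offsets.min() - 12.0 * sigma)
    hi = float(offsets.max() + 12.0 * sigma)

    def cdf(z: float) -> float:
        return float(ndtr((z - offsets) / sigma).mean()) - q

    return float(brentq(cdf, lo, hi, xtol=1e-12))


def generate(config: SyntheticConfig) -> tuple[MeasurementTable, GroundTruth]:
    """Draw one measurement table and its ground truth from ``config``."""
    panel = default_panel(config.panel_spec)
    samples = sorted(
        SampleKey(org, tis, prot, rep)
        for (org, tis) in config.matrices
        for prot in config.protocols
        for rep in range(1, config.replicates + 1)
    )
    n_samples = len(samples)
    sample_protocols = np.array([s.protocol for s in samples])
    protocols = list(config.protocols)

    # per-class precomputation: noise SD, per-protocol effect offsets and the
    # LOD placement (relative to baseline) from the analytic log2 marginal
    class_sigma = {c: config.sigma_log2(c) for c in config.panel_spec}
    class_eff = {
        c: np.array(
            [config.protocol_effects.get((p, c), 0.0) for p in protocols]
        )
        for c in config.panel_spec
    }
    class_eff_per_sample = {
        c: np.array(
            [config.protocol_effects.get((p, c), 0.0) for p in sample_protocols]
        )
        for c in config.panel_spec
    }
    class_lod_rel = {
        c: _mixture_quantile(
            np.repeat(class_eff[c], len(config.matrices)),
            class_sigma[c],
            config.lod_quantile,
        )
        for c in config.panel_spec
    }
    class_loq_rel = {
        c: max(
            class_lod_rel[c],
            _mixture_quantile(
                np.repeat(class_eff[c], len(config.matrices)),
                class_sigma[c],
                config.loq_quantile,
            ),
        )
        for c in config.panel_spec
    }

    names = panel.names
    cls_of = panel.class_of()
    conc = np.empty((n_samples, len(names)))
    stat = np.empty((n_samples, len(names)), dtype=object)
    baselines = {}
    lod_linear = {}
    lo, hi = config.baseline_log2_mean_range

    for j, met in enumerate(names):
        c = cls_of[met]
        sigma = class_sigma[c]
        rng = _met_substream(config.seed, met)
        baseline = rng.uniform(lo, hi)
        noise = rng.normal(0.0, sigma, n_samples) if sigma > 0 else np.zeros(n_samples)
        missing = rng.random(n_samples) < config.missing_rate
        log2_vals = baseline + class_eff_per_sample[c] + noise
        vals = np.exp2(log2_vals)
        lod_log2 = baseline + class_lod_rel[c]
        loq_log2 = baseline + class_loq_rel[c]
        col_stat = np.where(
            log2_vals < lod_log2,
            QuantStatus.BELOW_LOD.value,
            np.where(
                log2_vals < loq_log2,
                QuantStatus.BELOW_LOQ.value,
                QuantStatus.VALID.value,
            ),
        ).astype(object)
        col_stat[missing] = QuantStatus.MISSING.value
        vals[missing] = np.nan
        conc[:, j] = vals
        stat[:, j] = col_stat
        baselines[met] = float(baseline)
        lod_linear[met] = float(2.0 ** lod_log2) if math.isfinite(lod_log2) else 0.0

    table = MeasurementTable.from_arrays(panel, samples, conc, stat)

    effects = pd.DataFrame(
        {p: [class_eff[cls_of[m]][i] for m in names]
         for i, p in enumerate(protocols)},
        index=names,
    )
    p_above = pd.DataFrame(index=names, columns=protocols, dtype=float)
    for j, met in enumerate(names):
        c = cls_of[met]
        sigma = class_sigma[c]
        rel = class_lod_rel[c]
        if not math.isfinite(rel):
            p_above.loc[met] = 1.0
        elif sigma == 0:
            p_above.loc[met] = (class_eff[c] >= rel).astype(float)
        else:
            p_above.loc[met] = 1.0 - ndtr((rel - class_eff[c]) / sigma)
    rule = DetectionRule()
    p_eff = p_above * (1.0 - config.missing_rate)
    need = rule.min_count(config.replicates)
    expected_det = pd.DataFrame(
        binom.sf(need - 1, config.replicates, p_eff.to_numpy()) >= 0.5,
        index=names,
        columns=protocols,
    )

    planted: dict[str, str | None] = {}
    for c in config.panel_spec:
        eff = class_eff[c]
        top = eff.max()
        winners = [protocols[i] for i in range(len(protocols)) if eff[i] == top]
        planted[c] = winners[0] if (top > 0 and len(winners) == 1) else None

    truth = GroundTruth(
        panel=panel,
        baselines=pd.Series(baselines),
        effects=effects,
        lod=pd.Series(lod_linear),
        p_above_lod=p_above,
        expected_detectable=expected_det,
        planted_winner=planted,
    )
    return table, truth


def plant_scenario(
    name: str,
    seed: int = 0,
    shift_sigmas: float = 4.0,
    winner_protocol: str = "MeOH/CHCl3/H2O",
    second_protocol: str = "75EtOH/MTBE",
    target_class: str = "amino acids",
    base_config: SyntheticConfig | None = None,
) -> SyntheticConfig:
    """Configs whose ground truth realizes a named study pattern.

    ``global_null``: no protocol effects, no censoring, no missingness —
    every protocol is truly optimal for every metabolite.
    ``one_winner``: one protocol's mean is raised by ``shift_sigmas``
    within-group SDs for every class.
    ``two_tied_winners``: two protocols share that raise.
    ``class_specific_winner``: the raise applies to a single compound class
    only (the amino-acid pattern of acidified acetonitrile extractions).
    """
    base = base_config if base_config is not None else SyntheticConfig()
    base = replace(
        base, seed=seed, lod_quantile=0.0, loq_quantile=0.0, missing_rate=0.0
    )
    if name == "global_null":
        return replace(base, protocol_effects={})

    def shift_for(cls: str) -> float:
        return shift_sigmas * base.sigma_log2(cls)

    if name == "one_winner":
        effects = {
            (winner_protocol, c): shift_for(c) for c in base.panel_spec
        }
        return replace(base, protocol_effects=effects)
    if name == "two_tied_winners":
        effects = {}
        for c in base.panel_spec:
            effects[(winner_protocol, c)] = shift_for(c)
            effects[(second_protocol, c)] = shift_for(c)
        return replace(base, protocol_effects=effects)
    if name == "class_specific_winner":
        if target_class not in base.panel_spec:
            raise ConfigError(f"unknown target class {target_class!r}")
        return replace(
            base,
            protocol_effects={(winner_protocol, target_class): shift_for(target_class)},
        )
    raise ConfigError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
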