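"""Synthetic gel-quantification data with the study's design constants.

No raw band tables accompany the kinetic experiments this package models,
so this module is the stand-in data source: it forward-simulates the
degradation scheme under the published experimental designs and overlays a
gel-densitometry observation model (multiplicative log-normal band noise
followed by per-lane renormalization, since quantified lanes are always
normalized to unit total).

Design constants built in as defaults:

* titration time points 7 s, 15 s, 30 s, 1, 2, 3, 5, 10 and 15 min;
* 1 nM labelled RNA with enzyme between 5 and 1,000 nM;
* pulse-chase with scavenger added at 3 min (5,000-fold excess, i.e. a
  final scavenger concentration of 5,000 nM) and postchase sampling at
  4, 5, 7.5 and 10 min;
* five titration replicates and four pulse-chase replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .forward_sim import (
    PulseChaseProtocol,
    TitrationProtocol,
    simulate_pulse_chase,
    simulate_timecourse,
    sort_band_table,
)
from .kinetic_scheme import KineticScheme, RateSet, StepRates, SubstrateLadder

__all__ = [
    "NoiseModel",
    "ReplicateDesign",
    "LadderRateProfile",
    "default_titration_protocol",
    "default_pulse_chase_protocol",
    "generate_titration",
    "generate_pulse_chase",
    "wt_like_profile",
    "wt_like_rateset",
    "wt_like_scheme",
    "variant_profile",
    "VARIANT_ANCHORS",
]

#: Published titration time grid, seconds.
DEFAULT_TIMES = (7.0, 15.0, 30.0, 60.0, 120.0, 180.0, 300.0, 600.0, 900.0)
#: Default enzyme concentration grid, nM (within the stated 5-1,000 range).
DEFAULT_CONCS = (5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0)


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise for quantified gel bands.

    Each band intensity is multiplied by an independent log-normal factor
    with unit mean and coefficient of variation ``band_cv``; lanes are then
    renormalized to unit total, emulating per-lane normalization of
    densitometry values.  ``floor`` optionally zeroes bands below a
    detection threshold before renormalizing.
    """

    band_cv: float = 0.05
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.band_cv < 0:
            raise ValueError("band_cv must be >= 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")

    def apply(self, table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        out = table.copy()
        if self.band_cv > 0:
            sigma = np.sqrt(np.log1p(self.band_cv**2))
            factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(out))
            out["fraction"] = out["fraction"] * factors
        if self.floor > 0:
            out.loc[out["fraction"] < self.floor, "fraction"] = 0.0
        sums = out.groupby(["dataset_id", "enzyme_conc_nM", "time_s"])["fraction"].transform("sum")
        out["fraction"] = np.where(sums > 0, out["fraction"] / sums, out["fraction"])
        return sort_band_table(out)


@dataclass(frozen=True)
class ReplicateDesign:
    """Number of independent repeats of an experiment (>= 1)."""

    n_replicates: int = 5

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def seeds(self, seed: int) -> list[int]:
        ss = np.random.SeedSequence(seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(self.n_replicates)]


def default_titration_protocol(
    enzyme_concs: Sequence[float] = DEFAULT_CONCS,
    include_t0: bool = False,
) -> TitrationProtocol:
    """The published titration design: nine time points, 1 nM RNA.

    ``include_t0`` prepends a zero-time lane (some gels include an input
    lane); the canonical nine listed time points are the default.
    """
    times = DEFAULT_TIMES if not include_t0 else (1e-9,) + DEFAULT_TIMES
    return TitrationProtocol(enzyme_concs=tuple(float(e) for e in enzyme_concs), times=times, rna_conc=1.0)


def default_pulse_chase_protocol(enzyme_conc: float = 50.0) -> PulseChaseProtocol:
    """Chase at 3 min to 5,000-fold scavenger; postchase at 4, 5, 7.5, 10 min."""
    return PulseChaseProtocol(
        enzyme_conc=float(enzyme_conc),
        prechase_times=(180.0,),
        postchase_times=(240.0, 300.0, 450.0, 600.0),
        rna_conc=1.0,
        chase_time=180.0,
        chase_fold_excess=5000.0,
    )


def _with_replicates(simulate, noise: NoiseModel, design: ReplicateDesign, seed: int, base_id: str) -> pd.DataFrame:
    tables = []
    clean = simulate(base_id)
    for r, rep_seed in enumerate(design.seeds(seed), start=1):
        rng = np.random.default_rng(rep_seed)
        rep = clean.copy()
        rep["dataset_id"] = f"{base_id}_rep{r}"
        tables.append(noise.apply(rep, rng))
    return sort_band_table(pd.concat(tables, ignore_index=True))


def generate_titration(
    scheme: KineticScheme,
    protocol: TitrationProtocol,
    noise: NoiseModel,
    design: ReplicateDesign,
    seed: int,
    dataset_id: str = "titration",
    include_product: bool = True,
) -> pd.DataFrame:
    """Noisy replicated titration band table (reproducible for a seed)."""
    return _with_replicates(
        lambda base: simulate_timecourse(scheme, protocol, base, include_product),
        noise, design, seed, dataset_id,
    )


def generate_pulse_chase(
    scheme: KineticScheme,
    protocol: PulseChaseProtocol,
    noise: NoiseModel,
    design: ReplicateDesign,
    seed: int,
    dataset_id: str = "pulse_chase",
    include_product: bool = True,
) -> pd.DataFrame:
    """Noisy replicated pulse-chase band table (reproducible for a seed)."""
    return _with_replicates(
        lambda base: simulate_pulse_chase(scheme, protocol, base, include_product),
        noise, design, seed, dataset_id,
    )


@dataclass(frozen=True)
class LadderRateProfile:
    """Smooth low-dimensional rate profile over a degradation ladder.

    The first step carries its own parameters (it is kinetically distinct:
    slow and distributive, acting as a commitment checkpoint).  Later steps
    follow smooth interpolations in a normalized ladder coordinate
    ``s`` (0 at the second step, 1 at the last cleavable length):

    * ``kf`` rises from ``second_kf`` to a peak ``peak_kf`` at fractional
      position ``peak_pos`` (the overhang mid-ladder, where translocation
      through single-stranded RNA is fastest), then falls to ``end_kf`` as
      the duplex is engaged and unwound;
    * ``koff_p`` declines log-linearly from ``second_koff`` to
      ``end_koff`` (the enzyme grips shorter intermediates ever tighter);
    * ``kon_p`` declines log-linearly to ``kon_end_frac`` of the first-step
      value (fewer 3' binding determinants on shorter RNA).

    Nonproductive binding is shared across lengths and parameterized by its
    half-saturation constant ``np_khalf`` and dissociation rate ``np_koff``.

    This same family serves as the generator anchor set and as the
    parameterization the global fit floats, so parameter recovery is a
    well-posed self-consistency experiment.
    """

    first_kf: float = 0.1        # 1/s
    first_p: float = 0.23        # first-step processivity
    first_khalf: float = 508.3   # productive K1/2 of the first step, nM
    np_khalf: float = 4.2        # nonproductive K1/2, nM (shared)
    np_koff: float = 5e-4        # nonproductive dissociation, 1/s (shared)
    peak_kf: float = 1.0         # 1/s
    second_kf: float = 0.3       # 1/s
    end_kf: float = 0.25         # 1/s
    second_koff: float = 0.15    # 1/s
    end_koff: float = 0.005      # 1/s
    kon_end_frac: float = 0.3    # kon_p at the last step relative to the first
    peak_pos: float = 0.3        # fractional ladder position of the kf peak

    @property
    def first_koff(self) -> float:
        return self.first_kf * (1 - self.first_p) / self.first_p

    @property
    def first_kon(self) -> float:
        return self.first_koff / self.first_khalf

    @property
    def np_kon(self) -> float:
        return self.np_koff / self.np_khalf

    def to_rateset(self, ladder: SubstrateLadder) -> RateSet:
        cleavable = ladder.cleavable_lengths
        steps: dict[int, StepRates] = {}
        np_kon = self.np_kon
        later = cleavable[1:]
        if later.size:
            s = (cleavable[1] - later) / max(cleavable[1] - cleavable[-1], 1)
            kf_interp = PchipInterpolator(
                [0.0, self.peak_pos, 1.0],
                np.log([self.second_kf, self.peak_kf, self.end_kf]),
            )
            kf_later = np.exp(kf_interp(s))
            koff_later = self.second_koff * (self.end_koff / self.second_koff) ** s
            kon_later = self.first_kon * self.kon_end_frac ** s
        steps[int(cleavable[0])] = StepRates(
            kon_p=self.first_kon, koff_p=self.first_koff, kf=self.first_kf,
            kon_np=np_kon, koff_np=self.np_koff,
        )
        for i, n in enumerate(later):
            steps[int(n)] = StepRates(
                kon_p=float(kon_later[i]), koff_p=float(koff_later[i]), kf=float(kf_later[i]),
                kon_np=np_kon, koff_np=self.np_koff,
            )
        return RateSet(steps)

    def to_scheme(self, full_length: int = 34, product_length: int = 5,
                  junction_length: int | None = 18) -> KineticScheme:
        ladder = SubstrateLadder(full_length, product_length, junction_length)
        return KineticScheme(ladder, self.to_rateset(ladder))


#: First-step anchors for the substrate and construct variants studied:
#: (first-step processivity, productive K1/2 nM, nonproductive K1/2 nM).
VARIANT_ANCHORS: dict[str, dict[str, float]] = {
    "wt": {"first_p": 0.23, "first_khalf": 508.3, "np_khalf": 4.2},
    "hairpinG": {"first_p": 0.16, "first_khalf": 508.3, "np_khalf": 4.2},
    "hairpinF": {"first_p": 0.21, "first_khalf": 508.3, "np_khalf": 4.2},
    "hairpinI": {"first_p": 0.28, "first_khalf": 508.3, "np_khalf": 4.2},
    "dCSD": {"first_p": 0.15, "first_khalf": 97.7, "np_khalf": 8.5, "first_kf": 0.05},
}


def wt_like_profile() -> LadderRateProfile:
    """Anchor profile for the wild-type enzyme on the 34-nt hairpin."""
    return LadderRateProfile()


def variant_profile(name: str) -> LadderRateProfile:
    """Anchor profile for a named substrate/construct variant."""
    try:
        return replace(LadderRateProfile(), **VARIANT_ANCHORS[name])
    except KeyError:
        raise KeyError(f"unknown variant {name!r}; known: {sorted(VARIANT_ANCHORS)}") from None


def wt_like_rateset(ladder: SubstrateLadder | None = None) -> RateSet:
    """Documented 34->5 rate set anchored to the wild-type first-step values.

    By construction the first-step processivity is exactly 0.23, the
    first-step productive K1/2 is exactly 508.3 nM and the (shared)
    nonproductive K1/2 is exactly 4.2 nM; later steps follow the smooth
    profile of :class:`LadderRateProfile` (processivity rising toward ~1
    through the single-stranded phase).  Absolute timescales put the
    substrate half-life at 25 nM enzyme inside the 15-minute window.
    """
    if ladder is None:
        ladder = SubstrateLadder(34, 5, 18)
    return wt_like_profile().to_rateset(ladder)


def wt_like_scheme() -> KineticScheme:
    return wt_like_profile().to_scheme()
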