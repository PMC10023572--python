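"""Reaction scheme for sequential 3'->5' single-nucleotide RNA degradation.

A structured RNA substrate of ``full_length`` nucleotides is shortened one
nucleotide at a time down to a terminal end product of ``product_length``
nucleotides.  At every intermediate length ``n`` the enzyme can associate
with the free RNA either *productively* (3' end engaged in the active site,
degradation can proceed) or *nonproductively* (bound but unable to cleave;
the complex must dissociate before a productive encounter is possible).
A productive complex at length ``n`` either cleaves the next nucleotide at
rate ``kf(n)`` -- remaining bound to the shortened RNA -- or dissociates at
rate ``koff_p(n)``.  The per-step commitment probability

    P(n) = kf(n) / (kf(n) + koff_p(n))

is the processivity of that step, and ``K1/2 = koff / kon`` is the
functional half-saturation constant of the corresponding binding mode.

Because the enzyme is kept in large excess over the labelled RNA
(single-turnover, pre-steady-state regime), association is pseudo first
order in enzyme concentration and the whole scheme is a linear system whose
infinitesimal generator is assembled by :func:`generator_matrix`.

Units, fixed package-wide: time in seconds, concentration in nM,
first-order rates in 1/s, second-order (association) rates in 1/(nM*s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

import numpy as np

__all__ = [
    "SubstrateLadder",
    "StepRates",
    "RateSet",
    "KineticScheme",
    "build_scheme",
    "processivity_from_rates",
    "khalf_from_rates",
    "generator_matrix",
    "state_labels",
]

RATE_NAMES = ("kon_p", "koff_p", "kf", "kon_np", "koff_np")


@dataclass(frozen=True)
class SubstrateLadder:
    """Contiguous ladder of RNA species lengths.

    Parameters
    ----------
    full_length:
        Length of the intact substrate in nucleotides.
    product_length:
        Length of the terminal, no-longer-degraded end product (default 5).
    junction_length:
        Optional length at which the single-stranded 3' overhang reaches the
        duplex junction; used only to report overhang coordinates
        ``p = length - junction_length`` (positive in the overhang, zero at
        the junction, negative inside the stem).
    """

    full_length: int
    product_length: int = 5
    junction_length: int | None = None

    def __post_init__(self) -> None:
        if self.product_length >= self.full_length:
            raise ValueError(
                f"product_length ({self.product_length}) must be smaller than "
                f"full_length ({self.full_length})"
            )
        if self.product_length < 1:
            raise ValueError("product_length must be >= 1")
        if self.junction_length is not None and not (
            self.product_length < self.junction_length <= self.full_length
        ):
            raise ValueError(
                "junction_length must satisfy product_length < junction_length "
                "<= full_length"
            )

    @property
    def lengths(self) -> np.ndarray:
        """All species lengths, descending (full_length .. product_length)."""
        return np.arange(self.full_length, self.product_length - 1, -1)

    @property
    def cleavable_lengths(self) -> np.ndarray:
        """Lengths that can still be shortened (everything above the product)."""
        return np.arange(self.full_length, self.product_length, -1)

    @property
    def n_cleavable(self) -> int:
        return self.full_length - self.product_length

    def overhang(self, length: int | np.ndarray) -> int | np.ndarray:
        """Overhang coordinate of a species (requires ``junction_length``)."""
        if self.junction_length is None:
            raise ValueError("ladder has no junction_length set")
        return np.asarray(length) - self.junction_length if np.ndim(length) else length - self.junction_length


@dataclass(frozen=True)
class StepRates:
    """Elementary rate constants of a single ladder step."""

    kon_p: float   # productive association, 1/(nM*s)
    koff_p: float  # productive dissociation, 1/s
    kf: float      # forward (cleavage/translocation) step, 1/s
    kon_np: float = 0.0   # nonproductive association, 1/(nM*s)
    koff_np: float = 0.0  # nonproductive dissociation, 1/s

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")
        if self.kon_p <= 0:
            raise ValueError("kon_p must be > 0 for every cleavable length")


class RateSet(Mapping[int, StepRates]):
    """Per-length elementary rate constants for all cleavable lengths."""

    def __init__(self, steps: Mapping[int, StepRates]):
        self._steps: Dict[int, StepRates] = {int(n): s for n, s in steps.items()}

    def __getitem__(self, length: int) -> StepRates:
        return self._steps[length]

    def __iter__(self):
        return iter(sorted(self._steps, reverse=True))

    def __len__(self) -> int:
        return len(self._steps)

    def __eq__(self, other) -> bool:
        return isinstance(other, RateSet) and self._steps == other._steps

    def array(self, name: str, lengths: Iterable[int] | None = None) -> np.ndarray:
        """Vector of one rate constant over ``lengths`` (descending default)."""
        if name not in RATE_NAMES:
            raise KeyError(f"unknown rate name {name!r}")
        ls = list(lengths) if lengths is not None else list(self)
        return np.array([getattr(self._steps[n], name) for n in ls], float)

    @classmethod
    def from_arrays(cls, lengths: Iterable[int], **arrays: Iterable[float]) -> "RateSet":
        ls = list(lengths)
        cols = {k: list(v) for k, v in arrays.items()}
        steps = {
            n: StepRates(**{k: cols[k][i] for k in cols}) for i, n in enumerate(ls)
        }
        return cls(steps)

    @classmethod
    def uniform(cls, lengths: Iterable[int], **rates: float) -> "RateSet":
        return cls({n: StepRates(**rates) for n in lengths})


@dataclass(frozen=True)
class KineticScheme:
    """A substrate ladder together with its per-step rate constants."""

    ladder: SubstrateLadder
    rates: RateSet

    def __post_init__(self) -> None:
        have = set(self.rates)
        need = set(int(n) for n in self.ladder.cleavable_lengths)
        if have != need:
            missing = sorted(need - have)
            extra = sorted(have - need)
            parts = []
            if missing:
                parts.append(f"missing rates for lengths {missing}")
            if extra:
                parts.append(f"rates given for non-cleavable lengths {extra}")
            raise ValueError("; ".join(parts))

    @property
    def n_states(self) -> int:
        return 3 * self.ladder.n_cleavable + 1

    def processivity(self, length: int) -> float:
        s = self.rates[length]
        return processivity_from_rates(s.kf, s.koff_p)

    def khalf_productive(self, length: int) -> float:
        s = self.rates[length]
        return khalf_from_rates(s.koff_p, s.kon_p)

    def khalf_nonproductive(self, length: int) -> float:
        s = self.rates[length]
        return khalf_from_rates(s.koff_np, s.kon_np)


def build_scheme(full_length: int, product_length: int, rates: RateSet | Mapping[int, StepRates],
                 junction_length: int | None = None) -> KineticScheme:
    """Validate and assemble a :class:`KineticScheme`.

    Raises ``ValueError`` for inconsistent lengths, missing/extra rate
    entries, or negative rates (enforced by :class:`StepRates`).
    """
    ladder = SubstrateLadder(full_length, product_length, junction_length)
    if not isinstance(rates, RateSet):
        rates = RateSet(rates)
    return KineticScheme(ladder, rates)


def processivity_from_rates(kf: float, koff: float) -> float:
    """Per-step commitment probability ``P = kf / (kf + koff)``."""
    if kf < 0 or koff < 0:
        raise ValueError("rates must be >= 0")
    if kf == 0 and koff == 0:
        raise ValueError("processivity undefined for kf = koff = 0")
    return kf / (kf + koff)


def khalf_from_rates(koff: float, kon: float) -> float:
    """Functional half-saturation constant ``K1/2 = koff / kon`` in nM."""
    if kon <= 0:
        raise ValueError("kon must be > 0")
    if koff < 0:
        raise ValueError("koff must be >= 0")
    return koff / kon


def state_labels(scheme: KineticScheme) -> list[tuple[str, int]]:
    """Ordered ``(kind, length)`` labels matching :func:`generator_matrix` rows.

    Kinds are ``"free"``, ``"prod"`` (productive complex) and ``"nonprod"``;
    the final state is the absorbing free end product.
    """
    labels: list[tuple[str, int]] = []
    for n in scheme.ladder.cleavable_lengths:
        labels += [("free", int(n)), ("prod", int(n)), ("nonprod", int(n))]
    labels.append(("free", int(scheme.ladder.product_length)))
    return labels


def generator_matrix(scheme: KineticScheme, enzyme_conc: float) -> np.ndarray:
    """Infinitesimal generator of the pseudo-first-order degradation system.

    States are ordered as in :func:`state_labels`.  With state vector ``x``
    the dynamics are ``dx/dt = Q @ x``; columns of ``Q`` sum to zero
    (probability conservation) and off-diagonal entries are nonnegative.

    Transitions encoded, for each cleavable length ``n``:

    * free(n)    -> prod(n)      at ``kon_p(n) * E``
    * free(n)    -> nonprod(n)   at ``kon_np(n) * E``
    * prod(n)    -> free(n)      at ``koff_p(n)``
    * nonprod(n) -> free(n)      at ``koff_np(n)``
    * prod(n)    -> prod(n-1)    at ``kf(n)`` (enzyme stays bound), or to the
      absorbing free end product when ``n - 1`` is the product length.
    """
    if enzyme_conc < 0:
        raise ValueError("enzyme_conc must be >= 0")
    C = scheme.ladder.n_cleavable
    N = 3 * C + 1
    Q = np.zeros((N, N))
    product_idx = 3 * C

    def add(i: int, j: int, rate: float) -> None:
        # flux j -> i at given rate
        Q[i, j] += rate
        Q[j, j] -= rate

    for i, n in enumerate(scheme.ladder.cleavable_lengths):
        s = scheme.rates[int(n)]
        free, prod, nonp = 3 * i, 3 * i + 1, 3 * i + 2
        add(prod, free, s.kon_p * enzyme_conc)
        add(nonp, free, s.kon_np * enzyme_conc)
        add(free, prod, s.koff_p)
        add(free, nonp, s.koff_np)
        target = 3 * (i + 1) + 1 if i + 1 < C else product_idx
        add(target, prod, s.kf)
    return Q
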