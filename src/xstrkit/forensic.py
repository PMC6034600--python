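"""Forensic-efficiency parameters of X-STR loci.

All eight per-locus statistics are closed forms in the power sums
``Qk = sum_i p_i^k`` of the (pooled) allele-frequency vector:

* ``Het`` — expected heterozygosity (gene diversity), ``1 - Q2``.
* ``PDM`` — power of discrimination among male hemizygotes; identical to
  ``Het``: two random male X chromosomes differ with probability ``1 - Q2``.
* ``PDF`` — power of discrimination among female genotypes,
  ``1 - 2*Q2^2 + Q4``.
* ``PIC`` — polymorphism information content, ``1 - Q2 - Q2^2 + Q4``.
* ``PE`` — power of exclusion, the heterozygosity-based form
  ``H^2 * (1 - 2*H*(1-H)^2)`` with ``H = Het``.
* ``MEC_Kishida`` — mean exclusion chance for a mother/daughter/alleged-father
  trio with an X marker; equals PIC.
* ``MEC_DesmaraisDuo`` — mean exclusion chance for a father/daughter duo with
  a hemizygous alleged father, ``1 - 2*Q2 + Q3`` (the probability that a
  random man's single X allele is absent from a random daughter's genotype).
* ``MEC_Kruger`` — mean exclusion chance for deficiency cases, the classical
  trio exclusion power ``1 - 2*Q2 + Q3 + 3*(Q2*Q3 - Q5) - 2*(Q2^2 - Q4)``.

Cumulative (multi-locus) versions are ``1 - prod(1 - v_l)``; the complement is
carried in extended precision because a 19-locus panel drives it below 1e-20,
far past double rounding when printed as ``0.999...``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, getcontext
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PowerSums",
    "ForensicParams",
    "power_sums",
    "pe_from_heterozygosity",
    "locus_params",
    "cumulative",
    "cumulative_complement",
    "format_cumulative",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class PowerSums:
    """Moments Qk = sum p_i^k of a frequency vector (Q5 feeds the
    deficiency-case exclusion chance)."""

    q2: float
    q3: float
    q4: float
    q5: float


@dataclass(frozen=True)
class ForensicParams:
    pic: float
    het: float
    pe: float
    pdf: float
    pdm: float
    mec_kruger: float
    mec_kishida: float
    mec_desmarais_duo: float

    _FIELDS = (
        "pic", "het", "pe", "pdf", "pdm",
        "mec_kruger", "mec_kishida", "mec_desmarais_duo",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self._FIELDS}


def _check_freqs(freqs: Sequence[float] | Mapping) -> np.ndarray:
    if isinstance(freqs, Mapping):
        p = np.asarray(list(freqs.values()), dtype=float)
    else:
        p = np.asarray(list(freqs), dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(p < 0):
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def power_sums(freqs: Sequence[float] | Mapping) -> PowerSums:
    """Power sums Q2..Q5 of a probability vector."""
    p = _check_freqs(freqs)
    return PowerSums(
        q2=float(np.sum(p**2)),
        q3=float(np.sum(p**3)),
        q4=float(np.sum(p**4)),
        q5=float(np.sum(p**5)),
    )


def pe_from_heterozygosity(h: float) -> float:
    """Power of exclusion from expected heterozygosity: H^2 (1 - 2H(1-H)^2)."""
    if not 0.0 <= h < 1.0:
        raise ValueError(f"heterozygosity out of [0,1): {h}")
    return h * h * (1.0 - 2.0 * h * (1.0 - h) ** 2)


def locus_params(freqs: Sequence[float] | Mapping) -> ForensicParams:
    """The eight forensic-efficiency parameters of one locus."""
    q = power_sums(freqs)
    het = 1.0 - q.q2
    pic = 1.0 - q.q2 - q.q2**2 + q.q4
    pdf = 1.0 - 2.0 * q.q2**2 + q.q4
    duo = 1.0 - 2.0 * q.q2 + q.q3
    kruger = duo + 3.0 * (q.q2 * q.q3 - q.q5) - 2.0 * (q.q2**2 - q.q4)
    return ForensicParams(
        pic=pic,
        het=het,
        pe=pe_from_heterozygosity(het),
        pdf=pdf,
        pdm=het,
        mec_kruger=kruger,
        mec_kishida=pic,
        mec_desmarais_duo=duo,
    )


def cumulative_complement(values: Iterable[float]) -> float:
    """prod(1 - v) over per-locus probabilities, accumulated in log space."""
    total = 0.0
    for v in values:
        if not 0.0 <= v < 1.0:
            raise ValueError(f"per-locus probability out of [0,1): {v}")
        total += math.log1p(-v)
    return math.exp(total)


def cumulative(values: Iterable[float]) -> float:
    """Combined probability over loci: 1 - prod(1 - v).

    Returns 1.0 (to double precision) for strong panels; use
    :func:`cumulative_complement` or :func:`format_cumulative` when the tail
    matters.
    """
    return -math.expm1(math.log(cumulative_complement(values)))


def format_cumulative(values: Iterable[float], digits: int = 40) -> str:
    """Decimal string of 1 - prod(1 - v) at full printable precision.

    A 19-locus discrimination power can be 1 - 1.1e-22; the complement is
    exact to double precision, and the subtraction is done in ``Decimal`` so
    the long run of nines prints correctly.
    """
    comp = cumulative_complement(values)
    # the complement is only good to double precision; keep 17 significant
    # digits so the printed tail is not binary representation noise
    getcontext().prec = digits + 10
    comp_dec = Decimal(f"{comp:.16e}")
    return str(Decimal(1) - comp_dec)


def panel_report(
    per_locus: Mapping[str, ForensicParams]
) -> tuple["pd.DataFrame", dict[str, str]]:
    """Table of per-locus parameters (4 decimals) plus cumulative statistics.

    The cumulatives combine PDF, PDM and the three mean exclusion chances
    across loci and are reported at full precision.
    """
    import pandas as pd

    rows = []
    for locus, fp in per_locus.items():
        row = {"locus": locus}
        row.update({k: round(v, 4) for k, v in fp.as_dict().items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    cumulatives = {
        name: format_cumulative(
            [getattr(fp, name) for fp in per_locus.values()]
        )
        for name in ("pdf", "pdm", "mec_kruger", "mec_kishida", "mec_desmarais_duo")
    }
    return df, cumulatives
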