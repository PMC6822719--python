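"""Significance tests on smoothed-logit-transformed fractions.

Per-plate response fractions are mapped to the log-odds scale with a
smoothing constant ``c`` added to both numerator and denominator of the
odds, ``ln((f + c) / (1 - f + c))``, which keeps fractions of 0 and 1
finite.  The ``auto`` rule sets ``c`` to the smallest non-zero per-plate
fraction of the response in the dataset (0.1 for 10-seed plates whenever
some plate has a single positive count).

Two tests operate on the transformed values:

* a pooled-variance two-sample t-test of each inoculated cell against its
  control cell, and
* a balanced split-plot ANOVA with the Petri plate as the whole-plot
  (random) unit: strain varies between plates and is tested against the
  plate-within-strain mean square; species and the strain x species
  interaction vary within plates and are tested against the sub-plot
  residual.  A significant interaction is the signature of host-specific
  fungal effects.

No familywise-error correction is applied anywhere; all p-values are raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .effects import cell_fractions, fraction
from .plates import (
    CONTROL,
    Dataset,
    DesignError,
    ResponseKind,
    SeedFateError,
    Species,
    Temperature,
)

__all__ = [
    "SmoothedLogitParams",
    "TTestResult",
    "AnovaRow",
    "AnovaTable",
    "smoothed_logit",
    "smoothed_logit_fraction",
    "auto_smoothing_constant",
    "t_test_vs_control",
    "splitplot_anova",
]


@dataclass(frozen=True)
class SmoothedLogitParams:
    """Smoothing constant plus the rule that produced it."""

    c: float
    rule: str = "fixed"  # "fixed" or "auto"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise SeedFateError(f"smoothing constant must be > 0, got {self.c}")
        if self.rule not in ("fixed", "auto"):
            raise SeedFateError(f"unknown smoothing rule {self.rule!r}")


def smoothed_logit_fraction(f: float, c: float) -> float:
    """``ln((f + c) / (1 - f + c))`` — finite at f = 0 and f = 1, odd about 1/2."""
    if c <= 0:
        raise SeedFateError(f"smoothing constant must be > 0, got {c}")
    return math.log((f + c) / (1.0 - f + c))


def smoothed_logit(x: int, n: int, c: float) -> float:
    """Smoothed logit of a count ``x`` out of ``n``."""
    if not 0 <= x <= n:
        raise SeedFateError(f"count {x} outside [0, {n}]")
    return smoothed_logit_fraction(x / n, c)


def auto_smoothing_constant(
    dataset: Dataset,
    temperature: Temperature,
    response: ResponseKind,
) -> float:
    """Smallest non-zero per-plate fraction of ``response`` under ``temperature``."""
    temperature = Temperature(temperature)
    fractions = [
        fraction(r, response)
        for r in dataset.records
        if r.temperature == temperature
    ]
    positive = [f for f in fractions if f > 0]
    if not positive:
        raise DesignError(
            f"all {ResponseKind(response).value} fractions are zero under "
            f"{temperature.value}; no auto smoothing constant exists"
        )
    return min(positive)


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance t-test of one inoculated cell against control."""

    group: str
    species: Species
    temperature: Temperature
    response: ResponseKind
    effect_logit: float  # difference of cell means on the transformed scale
    se: float
    t_stat: float
    df: int
    p_value: float
    degenerate: bool = False  # zero pooled variance


def t_test_vs_control(
    dataset: Dataset,
    group: str,
    species: Species,
    temperature: Temperature,
    response: ResponseKind,
    c: float,
) -> TTestResult:
    """Two-sided pooled-variance t-test on smoothed-logit per-plate values."""
    if group == CONTROL:
        raise SeedFateError("t_test_vs_control requires a non-control group")
    ft = cell_fractions(dataset, group, species, temperature, response)
    fc = cell_fractions(dataset, CONTROL, species, temperature, response)
    if ft.size < 2 or fc.size < 2:
        raise DesignError(
            f"t-test needs >= 2 replicates per cell (got {ft.size} and {fc.size})"
        )
    yt = np.array([smoothed_logit_fraction(f, c) for f in ft])
    yc = np.array([smoothed_logit_fraction(f, c) for f in fc])
    n1, n2 = yt.size, yc.size
    diff = float(yt.mean() - yc.mean())
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * yt.var(ddof=1) + (n2 - 1) * yc.var(ddof=1)) / df
    # identical plate values can leave round-off dust in the variance;
    # degeneracy means "no within-cell spread in the data"
    degenerate = (yt.max() - yt.min() == 0.0) and (yc.max() - yc.min() == 0.0)
    if degenerate:
        sp2 = 0.0
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if degenerate:
        if diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.inf if diff > 0 else -math.inf
            p = 0.0
    else:
        t_stat = diff / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return TTestResult(
        group=group,
        species=Species(species),
        temperature=Temperature(temperature),
        response=ResponseKind(response),
        effect_logit=diff,
        se=se,
        t_stat=t_stat,
        df=df,
        p_value=p,
        degenerate=degenerate,
    )


# -- split-plot ANOVA -----------------------------------------------------


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float
    f: Optional[float] = None
    p: Optional[float] = None


@dataclass(frozen=True)
class AnovaTable:
    """Balanced split-plot decomposition of the transformed responses.

    Rows: strain (whole plot), plate-within-strain (whole-plot error),
    species, strain x species, residual (sub-plot error).
    """

    temperature: Temperature
    response: ResponseKind
    smoothing_constant: float
    rows: tuple[AnovaRow, ...]
    degenerate: bool = False  # all responses constant: F undefined

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    @property
    def interaction(self) -> AnovaRow:
        return self.row("strain:species")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "ss": r.ss,
                    "df": r.df,
                    "ms": r.ms,
                    "F": r.f if r.f is not None else float("nan"),
                    "p": r.p if r.p is not None else float("nan"),
                }
                for r in self.rows
            ]
        )


def splitplot_anova(
    dataset: Dataset,
    temperature: Temperature,
    response: ResponseKind,
    c: float,
) -> AnovaTable:
    """Split-plot ANOVA of strain, species and their interaction.

    CONTROL plates are excluded: the factor under test is the identity of
    the inoculated strain, and the whole-plot df then equals S - 1 for S
    strains.  Requires a balanced design (every strain with the same
    number of replicate plates, both species on each plate); the
    sums-of-squares decomposition below is exact only in that case.
    """
    temperature = Temperature(temperature)
    response = ResponseKind(response)
    strains = dataset.strains()
    if len(strains) < 2:
        raise DesignError("split-plot ANOVA needs >= 2 strains")
    reps = {s: sorted({r.replicate for r in dataset.records
                       if r.group == s and r.temperature == temperature})
            for s in strains}
    r0 = reps[strains[0]]
    if len(r0) < 2 or any(reps[s] != r0 for s in strains):
        raise DesignError(
            "unbalanced design: every strain needs the same >= 2 replicate "
            f"plates under {temperature.value}"
        )
    species = sorted(Species, key=lambda s: s.value)
    S, R = len(strains), len(r0)
    # y[s, r, k]: transformed fraction for strain s, replicate plate r, species k
    y = np.empty((S, R, 2), dtype=float)
    for i, strain in enumerate(strains):
        for k, sp in enumerate(species):
            fr = cell_fractions(dataset, strain, sp, temperature, response)
            y[i, :, k] = [smoothed_logit_fraction(f, c) for f in fr]

    grand = y.mean()
    m_strain = y.mean(axis=(1, 2))          # (S,)
    m_plate = y.mean(axis=2)                # (S, R)
    m_species = y.mean(axis=(0, 1))         # (2,)
    m_sx = y.mean(axis=1)                   # (S, 2)

    ss_strain = 2 * R * float(((m_strain - grand) ** 2).sum())
    ss_plate = 2 * float(((m_plate - m_strain[:, None]) ** 2).sum())
    ss_species = S * R * float(((m_species - grand) ** 2).sum())
    ss_inter = R * float(
        ((m_sx - m_strain[:, None] - m_species[None, :] + grand) ** 2).sum()
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - ss_strain - ss_plate - ss_species - ss_inter
    ss_resid = max(ss_resid, 0.0)  # guard tiny negative round-off

    df_strain, df_plate = S - 1, S * (R - 1)
    df_species, df_inter, df_resid = 1, S - 1, S * (R - 1)

    degenerate = ss_total == 0.0

    def _row(source, ss, df, ms_den=None, df_den=None):
        ms = ss / df if df > 0 else float("nan")
        if ms_den is None or degenerate or ms_den == 0.0:
            f = p = None
        else:
            f = ms / ms_den
            p = float(stats.f.sf(f, df, df_den))
        return AnovaRow(source=source, ss=ss, df=df, ms=ms, f=f, p=p)

    ms_plate = ss_plate / df_plate
    ms_resid = ss_resid / df_resid
    rows = (
        _row("strain", ss_strain, df_strain, ms_plate, df_plate),
        _row("plate(strain)", ss_plate, df_plate),
        _row("species", ss_species, df_species, ms_resid, df_resid),
        _row("strain:species", ss_inter, df_inter, ms_resid, df_resid),
        _row("residual", ss_resid, df_resid),
    )
    assert df_strain + df_plate + df_species + df_inter + df_resid == 2 * S * R - 1
    return AnovaTable(
        temperature=temperature,
        response=response,
        smoothing_constant=c,
        rows=rows,
        degenerate=degenerate,
    )
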