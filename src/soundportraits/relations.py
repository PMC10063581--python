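"""Correlations between concept score tables and dependent-correlation tests.

Within a rater group, the four concept score tables are correlated pairwise
over stimuli (Pearson).  Because such correlations share the same sample of
sounds, differences between them are tested with Steiger's (1980) Z: both
correlations are Fisher-z transformed and their difference is scaled by a
standard error that accounts for the dependence, using the pooled-correlation
covariance term.  Two variants are provided: ``overlapping`` compares r(a,b)
with r(a,c) (one shared variable; requires r(b,c)), and ``nonoverlapping``
compares r(a,b) with r(c,d) (no shared variable; requires the four cross
correlations).  When all cross-correlations are zero the statistic reduces
to the classical two-independent-samples Fisher-z test.

Finally, the coupling between group consistency and model accuracy is
measured by correlating mean compliance with mean cross-validated R^2 over
the group-by-concept grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ScoreTable


@dataclass
class ConceptCorrelations:
    group: str
    pairs: dict[tuple[str, str], tuple[float, float, int]]  # (r, p, n)

    def matrix(self) -> pd.DataFrame:
        concepts = sorted({c for pair in self.pairs for c in pair})
        m = pd.DataFrame(np.eye(len(concepts)), index=concepts, columns=concepts)
        for (a, b), (r, _, _) in self.pairs.items():
            m.loc[a, b] = m.loc[b, a] = r
        return m


@dataclass
class SteigerResult:
    z: float
    p: float
    n: int
    variant: str

    def text(self) -> str:
        # report df as n - 1 in the rendered form, matching the common
        # "Z(df)" reporting style; the SE itself uses n
        return f"Z({self.n - 1}) = {self.z:.2f}, p = {self.p:.3g}"


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson r with t-distribution p-value (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)


def concept_correlations(score_tables: Mapping[str, ScoreTable], group: str = "") -> ConceptCorrelations:
    """Pairwise Pearson correlations between concept score tables."""
    concepts = sorted(score_tables)
    pairs = {}
    for a, b in itertools.combinations(concepts, 2):
        sa = score_tables[a].series()
        sb = score_tables[b].series().loc[sa.index]
        pairs[(a, b)] = pearson_r(sa.to_numpy(), sb.to_numpy())
    return ConceptCorrelations(group=group, pairs=pairs)


def _fisher_z(r: float) -> float:
    return float(np.arctanh(r))


def steiger_compare(
    r_ab: float,
    r_cd: float,
    cross_correlations: Mapping[str, float],
    n: int,
    variant: str = "overlapping",
) -> SteigerResult:
    """Steiger's Z for the difference of two dependent correlations.

    ``overlapping``: r_ab vs r_ac share variable a; supply ``{"r_bc": ...}``.
    ``nonoverlapping``: r_ab vs r_cd share none; supply ``r_ac, r_ad, r_bc,
    r_bd``.  Two-sided p from the standard normal.
    """
    for name, r in (("r_ab", r_ab), ("r_cd", r_cd)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    rbar = 0.5 * (r_ab + r_cd)
    if variant == "overlapping":
        if "r_bc" not in cross_correlations:
            raise ValueError("overlapping variant requires cross correlation r_bc")
        r_bc = cross_correlations["r_bc"]
        psi = r_bc * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (
            1.0 - 2.0 * rbar**2 - r_bc**2
        )
        cov = psi / (1.0 - rbar**2) ** 2
    elif variant == "nonoverlapping":
        missing = {"r_ac", "r_ad", "r_bc", "r_bd"} - set(cross_correlations)
        if missing:
            raise ValueError(f"nonoverlapping variant requires {sorted(missing)}")
        r_ac = cross_correlations["r_ac"]
        r_ad = cross_correlations["r_ad"]
        r_bc = cross_correlations["r_bc"]
        r_bd = cross_correlations["r_bd"]
        psi = (
            0.5 * rbar * rbar * (r_ac**2 + r_ad**2 + r_bc**2 + r_bd**2)
            + r_ac * r_bd
            + r_ad * r_bc
            - rbar * (r_ac * r_ad + r_bc * r_bd)
            - rbar * (r_ac * r_bc + r_ad * r_bd)
        )
        cov = psi / (1.0 - rbar**2) ** 2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    z = (_fisher_z(r_ab) - _fisher_z(r_cd)) * np.sqrt((n - 3) / (2.0 - 2.0 * cov))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(z=float(z), p=p, n=n, variant=variant)


def consistency_accuracy_correlation(
    compliance_by_cell: Mapping[tuple[str, str], float],
    r2_by_cell: Mapping[tuple[str, str], float],
) -> tuple[float, float, int]:
    """Pearson r between mean compliance and mean R^2 over group x concept cells."""
    if set(compliance_by_cell) != set(r2_by_cell):
        raise ValueError("cell sets differ")
    cells = sorted(compliance_by_cell)
    if len(cells) < 3:
        raise ValueError("need at least 3 cells")
    x = [compliance_by_cell[c] for c in cells]
    y = [r2_by_cell[c] for c in cells]
    return pearson_r(x, y)
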