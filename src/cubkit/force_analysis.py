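"""ENC-plot, Parity Rule 2, and neutrality regression.

These three views jointly partition codon usage bias between directional
mutation pressure and natural selection:

* ENC-plot: observed ENC against GC3 compared with the mutation-only null
  curve ENC_exp(s) = 2 + s + 29/(s^2 + (1-s)^2); points below the curve
  indicate forces beyond composition.
* PR2: within fourfold-degenerate codon boxes mutation pressure alone
  predicts A=T and G=C at the third position, i.e. the point
  (G3/(G3+C3), A3/(A3+T3)) = (0.5, 0.5).
* Neutrality plot: ordinary least squares of GC12 on GC3; slope near 1
  means mutation-driven, near 0 selection-driven, and |slope|*100 is
  read as the mutation-pressure percentage.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import count_codons, enc
from .composition import composition_profile
from .genetic_code import FOURFOLD_BOXES
from .seq_io import CodingSequence, CubkitError

logger = logging.getLogger(__name__)

SitePolicy = Literal["fourfold", "all"]


def expected_enc(s: float | np.ndarray) -> float | np.ndarray:
    """Wright's mutation-only null ENC at third-position GC content ``s``."""
    s = np.asarray(s, dtype=float)
    out = 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)
    return float(out) if out.ndim == 0 else out


def expected_enc_curve(resolution: int = 101) -> pd.DataFrame:
    """The null curve sampled on [0, 1] for plotting."""
    s = np.linspace(0.0, 1.0, resolution)
    return pd.DataFrame({"gc3": s, "expected_enc": expected_enc(s)})


def enc_plot(seqs: Sequence[CodingSequence]) -> pd.DataFrame:
    """One ENC-plot point per sequence: GC3 (proportion), observed and
    expected ENC, and the relative deviation (expected-observed)/expected.

    Sequences with undefined ENC are omitted with a log entry.
    """
    rows = []
    for s in seqs:
        e = enc(count_codons(s))
        if not e.defined:
            logger.warning("ENC undefined for %s; point omitted", s.id)
            continue
        gc3 = composition_profile(s).gc3 / 100.0
        exp = expected_enc(gc3)
        rows.append(
            {
                "id": s.id,
                "host": s.host,
                "region": s.region,
                "gc3": gc3,
                "enc": e.enc,
                "expected_enc": exp,
                "deviation": (exp - e.enc) / exp,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PR2Point:
    """Third-position parity coordinates for one sequence.

    ``x`` = G3/(G3+C3), ``y`` = A3/(A3+T3); a coordinate is ``nan`` with its
    flag cleared when the denominator is zero.
    """

    id: str
    x: float
    y: float
    x_defined: bool
    y_defined: bool
    a3: int
    t3: int
    g3: int
    c3: int


def pr2(cds: CodingSequence, site_policy: SitePolicy = "fourfold") -> PR2Point:
    """Parity Rule 2 coordinates of one CDS.

    ``site_policy`` selects the assessed third positions: ``fourfold``
    (default) restricts to the eight codon boxes whose third position is
    fully synonymous, the classical PR2 formulation; ``all`` uses every
    codon's third position.
    """
    counts: Counter = Counter()
    for codon in cds.codons:
        if site_policy == "fourfold" and codon[:2] not in FOURFOLD_BOXES:
            continue
        counts[codon[2]] += 1
    a3, t3, g3, c3 = counts["A"], counts["T"], counts["G"], counts["C"]
    gx = g3 + c3
    ay = a3 + t3
    return PR2Point(
        id=cds.id,
        x=g3 / gx if gx else float("nan"),
        y=a3 / ay if ay else float("nan"),
        x_defined=gx > 0,
        y_defined=ay > 0,
        a3=a3,
        t3=t3,
        g3=g3,
        c3=c3,
    )


def pr2_table(
    seqs: Sequence[CodingSequence], site_policy: SitePolicy = "fourfold"
) -> pd.DataFrame:
    rows = []
    for s in seqs:
        p = pr2(s, site_policy)
        rows.append(
            {"id": s.id, "host": s.host, "region": s.region,
             "x_g3_gc3": p.x, "y_a3_at3": p.y,
             "x_defined": p.x_defined, "y_defined": p.y_defined}
        )
    df = pd.DataFrame(rows)
    df.attrs["site_policy"] = site_policy
    return df


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with its force partition.

    Slope/intercept are on whatever scale the inputs share ([0,1] here);
    ``mutation_pct`` = |slope|*100 and ``selection_pct`` its complement,
    summing to 100 exactly.
    """

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    group: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.slope)

    @property
    def mutation_pct(self) -> float:
        return abs(self.slope) * 100.0

    @property
    def selection_pct(self) -> float:
        return 100.0 - self.mutation_pct


def neutrality_fit(
    gc3: np.ndarray, gc12: np.ndarray, group: str = ""
) -> NeutralityFit:
    """Least-squares GC12 ~ GC3 with Pearson r and its exact two-sided
    p-value (t-transform, n-2 df)."""
    gc3 = np.asarray(gc3, dtype=float)
    gc12 = np.asarray(gc12, dtype=float)
    if gc3.size < 3:
        raise CubkitError(f"group {group!r}: need >= 3 sequences for regression")
    if np.ptp(gc3) == 0:
        return NeutralityFit(
            slope=float("nan"), intercept=float("nan"), r=float("nan"),
            p_value=float("nan"), n=int(gc3.size), group=group,
        )
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(gc3.size),
        group=group,
    )


def neutrality(
    seqs: Sequence[CodingSequence],
    group_by: Sequence[str] | None = ("region",),
) -> list[NeutralityFit]:
    """Per-group neutrality regressions over per-sequence (GC3, GC12).

    ``group_by=None`` fits one regression over all sequences. Proportion
    scale [0, 1] internally; multiply by 100 for the %-scale plots.
    """
    rows = []
    for s in seqs:
        prof = composition_profile(s)
        rows.append(
            {**{k: getattr(s, k) for k in (group_by or ())},
             "gc3": prof.gc3 / 100.0, "gc12": prof.gc12 / 100.0}
        )
    df = pd.DataFrame(rows)
    if not group_by:
        return [neutrality_fit(df["gc3"].to_numpy(), df["gc12"].to_numpy(), "all")]
    fits = []
    for key, grp in df.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        fits.append(
            neutrality_fit(
                grp["gc3"].to_numpy(), grp["gc12"].to_numpy(),
                group="|".join(str(k) for k in key),
            )
        )
    return fits


def force_partition(fit: NeutralityFit) -> tuple[float, float]:
    """(mutation %, selection %) read off a neutrality fit.

    Slope 1 is the pure-mutation limit (100, 0); slope 0 pure selection
    (0, 100). Undefined fits give (nan, nan).
    """
    if not fit.defined:
        return (float("nan"), float("nan"))
    return (fit.mutation_pct, fit.selection_pct)


def neutrality_table(fits: Sequence[NeutralityFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        mut, sel = force_partition(f)
        rows.append(
            {"group": f.group, "slope": f.slope, "intercept": f.intercept,
             "r": f.r, "p_value": f.p_value, "n": f.n,
             "mutation_pct": mut, "selection_pct": sel,
             "defined": f.defined}
        )
    return pd.DataFrame(rows)
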