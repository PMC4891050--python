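"""Hit triage on experimental readouts and dose-response quantification.

After the computational funnel, candidate compounds are triaged on two
orthogonal wet-lab readouts: direct target binding by surface plasmon
resonance (response units, RU) and functional suppression of MMP-2 secretion
from gelatin-zymography densitometry, quantified as

    inhibition ratio (%) = [1 - gray(treatment) / gray(control)] * 100 .

A compound advances on a readout only if it *strictly* exceeds the threshold
(RU > 20, inhibition > 30 % by default); the prize is the intersection of the
two hit lists.  Dimerization inhibition is quantified from gel densitometry
as the dimer band fraction, and dose-response potency by a four-parameter
logistic (4PL) least-squares fit

    y = bottom + (top - bottom) / (1 + (x / IC50)^hill) .
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ScreenRecord",
    "DoseResponseFit",
    "DensitometryPair",
    "inhibition_ratio",
    "triage_hits",
    "dimer_fraction",
    "relative_dimerization",
    "four_pl",
    "fit_4pl",
    "read_screen_records",
    "triage_report",
]

RU_MIN = 20.0
INH_MIN = 30.0


@dataclass(frozen=True)
class ScreenRecord:
    compound_id: str
    ru: float
    inhibition: float  # percent of control MMP-2 secretion inhibited

    def __post_init__(self):
        if self.inhibition > 100:
            raise ValueError("inhibition ratio cannot exceed 100%")


@dataclass(frozen=True)
class DensitometryPair:
    monomer_gray: float
    dimer_gray: float

    def __post_init__(self):
        if self.monomer_gray < 0 or self.dimer_gray < 0:
            raise ValueError("gray values must be >= 0")
        if self.monomer_gray == 0 and self.dimer_gray == 0:
            raise ValueError("monomer and dimer gray values cannot both be zero")


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    hill: float
    ic50: float
    rss: float
    converged: bool


# ---------------------------------------------------------------------------
# Readout arithmetic
# ---------------------------------------------------------------------------

def inhibition_ratio(gray_treatment: float, gray_control: float) -> float:
    """[1 - gray(treatment)/gray(control)] x 100, percent."""
    if gray_control <= 0:
        raise ValueError("control gray value must be > 0")
    if gray_treatment < 0:
        raise ValueError("treatment gray value must be >= 0")
    return (1.0 - gray_treatment / gray_control) * 100.0


def triage_hits(records: list[ScreenRecord], ru_min: float = RU_MIN,
                inh_min: float = INH_MIN) -> tuple[list[str], list[str], list[str]]:
    """(ru_hits, inhibition_hits, intersection) id lists, strict thresholds,
    input order preserved."""
    if not records:
        raise ValueError("no screen records supplied")
    ru_hits = [r.compound_id for r in records if r.ru > ru_min]
    inh_hits = [r.compound_id for r in records if r.inhibition > inh_min]
    inter = [r.compound_id for r in records
             if r.compound_id in ru_hits and r.compound_id in inh_hits]
    return ru_hits, inh_hits, inter


def dimer_fraction(pair: DensitometryPair) -> float:
    """dimer / (dimer + monomer) band-intensity fraction, in [0, 1]."""
    return pair.dimer_gray / (pair.dimer_gray + pair.monomer_gray)


def relative_dimerization(pair: DensitometryPair, control: DensitometryPair) -> float:
    """Dimer fraction normalized to the control lane's fraction."""
    f_ctrl = dimer_fraction(control)
    if f_ctrl <= 0:
        raise ValueError("control dimer fraction must be > 0")
    return dimer_fraction(pair) / f_ctrl


# ---------------------------------------------------------------------------
# 4PL dose-response fitting
# ---------------------------------------------------------------------------

def four_pl(x, bottom: float, top: float, hill: float, ic50: float):
    """The four-parameter logistic response at dose x."""
    x = np.asarray(x, float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def fit_4pl(doses, responses, max_iter: int = 200, tol: float = 1e-10) -> DoseResponseFit:
    """Least-squares 4PL fit with the fixed deterministic initialization
    bottom = min(y), top = max(y), hill = 1, IC50 = geometric-mean dose.

    IC50 is optimized on a log scale, so the fitted value is always positive.
    ``converged`` reflects the optimizer's gradient/step criterion at `tol`.
    """
    x = np.asarray(doses, float)
    y = np.asarray(responses, float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("doses and responses must be 1-D and equal length")
    if np.any(x <= 0):
        raise ValueError("doses must be > 0")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct doses to fit a 4PL")

    y_min, y_max = float(np.min(y)), float(np.max(y))
    p0 = np.array([y_min, y_max, 1.0, float(np.mean(np.log(x)))])

    def residuals(p):
        bottom, top, hill, log_ic50 = p
        return four_pl(x, bottom, top, hill, math.exp(log_ic50)) - y

    result = least_squares(residuals, p0, method="lm", max_nfev=max_iter * 10,
                           xtol=tol, ftol=tol, gtol=tol)
    bottom, top, hill, log_ic50 = result.x
    ic50 = math.exp(float(log_ic50))
    rss = float(np.sum(result.fun ** 2))
    degenerate = abs(top - bottom) < 1e-8 * max(1.0, abs(y_max - y_min), abs(y_max))
    converged = bool(result.status > 0) and not degenerate
    if bottom > top:  # report with bottom <= top; invert hill accordingly
        bottom, top, hill = top, bottom, -hill
    return DoseResponseFit(bottom=float(bottom), top=float(top), hill=float(hill),
                           ic50=ic50, rss=rss, converged=converged)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_screen_records(csv_text: str) -> list[ScreenRecord]:
    """CSV with columns compound_id, ru, inhibition."""
    df = pd.read_csv(io.StringIO(csv_text))
    required = {"compound_id", "ru", "inhibition"}
    if not required.issubset(df.columns):
        raise ValueError(f"screen-record CSV must have columns {sorted(required)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(ScreenRecord(str(row["compound_id"]),
                                        float(row["ru"]), float(row["inhibition"])))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"bad screen record in CSV row {i + 1}: {exc}") from exc
    return records


def triage_report(records: list[ScreenRecord], ru_min: float = RU_MIN,
                  inh_min: float = INH_MIN) -> str:
    """TSV report of the three hit lists plus a summary line."""
    ru_hits, inh_hits, inter = triage_hits(records, ru_min, inh_min)
    rows = ["list\tcount\tids",
            f"ru_hits\t{len(ru_hits)}\t{','.join(ru_hits)}",
            f"inhibition_hits\t{len(inh_hits)}\t{','.join(inh_hits)}",
            f"intersection\t{len(inter)}\t{','.join(inter)}",
            f"# {len(records)} records; RU > {ru_min:g}; inhibition > {inh_min:g}%"]
    return "\n".join(rows) + "\n"
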