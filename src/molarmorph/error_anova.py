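"""Procrustes ANOVA: hierarchical decomposition of measurement error.

In a replicated error study every individual is scanned s >= 2 times and
every scan digitized d >= 2 times, giving the nested hierarchy
individual > scan session > digitization. Variation is decomposed into
sums of squares at each level:

* ``size`` response: ordinary hierarchical ANOVA on centroid size.
* ``shape`` response: squared deviations of Procrustes coordinates
  pooled over all landmarks and dimensions (Goodall-style isotropic
  pooling), with each design degree of freedom multiplied by the shape
  dimension 3k - 7.

Each effect's mean square is tested against the next-lower stratum
(individual vs scan, scan vs digitization) with a parametric F test, and
the share of total variation per level is reported as SS / total SS.
A small total measurement share (scan + digitization) relative to the
individual share indicates that digitization noise is negligible against
true between-individual variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .landmark_io import StudyDataset
from .procrustes import SIMILARITY_DOF_3D, gpa

EFFECTS = ("individual", "scan_error", "digitization_error")


@dataclass
class ProcrustesAnovaTable:
    """Hierarchical ANOVA table with rows individual / scan / digitization.

    ``f`` and ``p`` are NaN for the lowest stratum, which has no error
    term below it.
    """

    response: str
    effects: tuple[str, ...]
    ss: np.ndarray
    df: np.ndarray
    ms: np.ndarray = field(default=None)  # type: ignore[assignment]
    f: np.ndarray = field(default=None)  # type: ignore[assignment]
    p: np.ndarray = field(default=None)  # type: ignore[assignment]
    percent_explained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ss = np.asarray(self.ss, dtype=float)
        self.df = np.asarray(self.df)
        if np.any(self.ss < 0):
            raise ValueError("sums of squares must be non-negative")
        if self.ms is None:
            self.ms = self.ss / self.df
        if self.percent_explained is None:
            self.percent_explained = 100.0 * self.ss / self.ss.sum()
        if self.f is None:
            f = np.full(len(self.effects), np.nan)
            p = np.full(len(self.effects), np.nan)
            for r in range(len(self.effects) - 1):
                f[r] = self.ms[r] / self.ms[r + 1]
                p[r] = stats.f.sf(f[r], self.df[r], self.df[r + 1])
            self.f, self.p = f, p

    @classmethod
    def from_components(
        cls, ss, df, response: str = "shape", effects: tuple[str, ...] = EFFECTS
    ) -> "ProcrustesAnovaTable":
        """Build a table from sums of squares and degrees of freedom alone.

        MS, F ratios, p-values and percent explained are derived, which
        makes printed SS/df columns reproducible as a worked example.
        """
        return cls(response=response, effects=tuple(effects), ss=ss, df=df)

    def row(self, effect: str) -> dict:
        i = self.effects.index(effect)
        return {
            "effect": effect,
            "percent_explained": float(self.percent_explained[i]),
            "ss": float(self.ss[i]),
            "ms": float(self.ms[i]),
            "df": int(self.df[i]),
            "f": float(self.f[i]),
            "p": float(self.p[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Effect": list(self.effects),
                "%Explained": self.percent_explained,
                "SS": self.ss,
                "MS": self.ms,
                "df": self.df,
                "F": self.f,
                "P": self.p,
            }
        )


def _individual_ids(dataset: StudyDataset, individual_ids) -> np.ndarray:
    if individual_ids is not None:
        return np.asarray(individual_ids)
    # error-study specimen ids are "<individual>:s<scan>:d<digit>"
    ids = []
    for sid in dataset.specimen_ids:
        ids.append(sid.split(":")[0])
    return np.array(ids)


def _check_design(ind: np.ndarray, scan: np.ndarray, digit: np.ndarray) -> tuple[int, int, int]:
    individuals = np.unique(ind)
    n_ind = len(individuals)
    scans_per_ind = {i: sorted(set(scan[ind == i])) for i in individuals}
    scan_counts = {len(v) for v in scans_per_ind.values()}
    if len(scan_counts) != 1:
        raise DesignError("unbalanced design: individuals differ in number of scan sessions")
    s = scan_counts.pop()
    digit_counts = set()
    for i in individuals:
        for sc in scans_per_ind[i]:
            digit_counts.add(int(np.sum((ind == i) & (scan == sc))))
    if len(digit_counts) != 1:
        raise DesignError("unbalanced design: scans differ in number of digitizations")
    d = digit_counts.pop()
    if s < 2 or d < 2:
        raise DesignError(
            f"need >= 2 scan sessions and >= 2 digitizations per scan, got s={s}, d={d}"
        )
    return n_ind, s, d


def procrustes_anova(
    dataset: StudyDataset,
    response: str = "shape",
    individual_ids=None,
) -> ProcrustesAnovaTable:
    """Hierarchical (Procrustes) ANOVA of a replicated error study.

    Parameters
    ----------
    dataset
        Configurations with complete ``scan_session`` and ``digitization``
        replicate labels. The individual behind each replicate is taken
        from the part of the specimen id before the first ``":"`` unless
        ``individual_ids`` supplies explicit labels.
    response
        ``"shape"`` pools squared Procrustes-coordinate deviations over
        landmarks and dimensions, multiplying design dfs by 3k - 7;
        ``"size"`` runs the ordinary hierarchical ANOVA on centroid size.
    """
    if response not in ("shape", "size"):
        raise ValueError("response must be 'shape' or 'size'")
    if not dataset.records:
        raise DesignError("dataset has no classifier records with replicate labels")
    scan = dataset.labels("scan_session")
    digit = dataset.labels("digitization")
    if any(v is None for v in scan) or any(v is None for v in digit):
        raise DesignError("replicate labels (scan_session, digitization) incomplete")
    scan = scan.astype(int)
    digit = digit.astype(int)
    ind = _individual_ids(dataset, individual_ids)
    n_ind, s, d = _check_design(ind, scan, digit)

    fit = gpa(dataset)
    if response == "size":
        Y = fit.centroid_sizes[:, None]
        mult = 1
    else:
        k = fit.n_landmarks
        Y = fit.aligned.reshape(len(dataset), 3 * k)
        mult = 3 * k - SIMILARITY_DOF_3D

    grand = Y.mean(axis=0)
    ss_ind = 0.0
    ss_scan = 0.0
    ss_digit = 0.0
    for i in np.unique(ind):
        rows_i = ind == i
        m_i = Y[rows_i].mean(axis=0)
        ss_ind += rows_i.sum() * float(np.sum((m_i - grand) ** 2))
        for sc in np.unique(scan[rows_i]):
            rows_is = rows_i & (scan == sc)
            m_is = Y[rows_is].mean(axis=0)
            ss_scan += rows_is.sum() * float(np.sum((m_is - m_i) ** 2))
            ss_digit += float(np.sum((Y[rows_is] - m_is) ** 2))

    df = np.array([(n_ind - 1) * mult, n_ind * (s - 1) * mult, n_ind * s * (d - 1) * mult])
    return ProcrustesAnovaTable(
        response=response, effects=EFFECTS, ss=np.array([ss_ind, ss_scan, ss_digit]), df=df
    )


def total_measurement_error(table: ProcrustesAnovaTable) -> float:
    """Total measurement share: percent explained summed over non-individual effects."""
    keep = [e != "individual" for e in table.effects]
    return float(np.sum(table.percent_explained[keep]))
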