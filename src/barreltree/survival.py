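"""Birth–death statistics of dendritic trees.

Trees emerge and disappear continually during the imaging window; this
module turns a :class:`~barreltree.registration.PresenceMatrix` into
right-censored survival records (one per newly formed tree), estimates
Kaplan–Meier survival curves with log(-log) 95% confidence bands, compares
inner vs outer trees by the log-rank test, computes one-frame elimination
fractions, classifies tree fates (surviving/eliminated x inside/outside)
and tabulates mean tree length against frames survived.

Time is measured in imaging frames (one frame = one 8-h interval between
consecutive sessions; the longer final interval counts as one frame).  A
tree present at exactly k sessions has lifetime k, so "disappeared by the
next imaging session" means lifetime 1.  Trees still present at the final
observed session are right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .registration import PresenceMatrix

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "SurvivalError",
    "derive_survival_records",
    "km_estimate",
    "logrank_test",
    "elimination_fraction",
    "classify_fate",
    "length_by_survival",
    "turnover_counts",
]


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalRecord:
    """Lifetime of one newly formed tree."""

    neuron_id: str
    tree_uid: str
    side: str                     # "inner" | "outer"
    birth_session: str
    lifetime: int                 # consecutive present sessions, >= 1
    censored: bool                # still present at the final session
    interval_censored: bool = False  # death time masked by an unknown cell


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with Greenwood log(-log) bands."""

    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray


def derive_survival_records(
    pm: PresenceMatrix,
    window: tuple[str, str] | None = None,
) -> list[SurvivalRecord]:
    """One record per tree newly formed inside ``window``.

    A tree is newly formed at session s when s is its first present cell,
    the preceding session exists and is not unknown (so pre-existing trees
    and trees first seen after a data gap are excluded).  ``window`` bounds
    the birth session (inclusive); default spans from the second session to
    the last.  Lifetime counts present cells; a tree whose first definite
    absence follows an unknown cell is flagged interval-censored and
    treated as dying at the first absence.
    """
    sessions = pm.sessions
    if window is None:
        window = (sessions[1], sessions[-1]) if len(sessions) > 1 else (
            sessions[0], sessions[-1]
        )
    lo, hi = sessions.index(window[0]), sessions.index(window[1])
    records = []
    for (nid, uid, side), row in pm.table.iterrows():
        cells = row.to_numpy()
        present = np.flatnonzero(cells == "P")
        if len(present) == 0:
            continue
        birth = int(present[0])
        # birth must be observed *as* a birth: previous session seen & absent
        if birth == 0 or cells[birth - 1] == "U":
            continue
        if not (lo <= birth <= hi):
            continue
        lifetime = int((cells == "P").sum())
        last_present = int(present[-1])
        censored = last_present == len(sessions) - 1
        interval = False
        if not censored:
            nxt = cells[last_present + 1 :]
            first_after = nxt[0] if len(nxt) else "A"
            if first_after == "U":
                interval = True
        records.append(
            SurvivalRecord(
                neuron_id=nid,
                tree_uid=uid,
                side=side,
                birth_session=sessions[birth],
                lifetime=lifetime,
                censored=censored,
                interval_censored=interval,
            )
        )
    return records


def _durations_events(records) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([r.lifetime for r in records], float)
    e = np.array([not r.censored for r in records], bool)
    return d, e


def km_estimate(records, alpha: float = 0.05) -> KMCurve:
    """Kaplan–Meier survival over frames survived.

    Product-limit estimator with Greenwood variance; the confidence band
    uses the exponential-Greenwood log(-log S) transform, which keeps the
    band inside [0, 1].
    """
    if not records:
        raise SurvivalError("no records")
    d, e = _durations_events(records)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(d, event_observed=e)
    times = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    ci = kmf.confidence_interval_
    lo = ci.iloc[:, 0].to_numpy(float)
    hi = ci.iloc[:, 1].to_numpy(float)
    at_risk = np.array(
        [int((d >= t).sum()) if t > 0 else len(d) for t in times]
    )
    return KMCurve(times=times, survival=surv, ci_low=lo, ci_high=hi, n_at_risk=at_risk)


def logrank_test(records_a, records_b) -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi2, p)`` with 1 df."""
    if not records_a or not records_b:
        raise SurvivalError("both groups need records")
    da, ea = _durations_events(records_a)
    db, eb = _durations_events(records_b)
    if ea.sum() + eb.sum() == 0:
        raise SurvivalError("log-rank undefined without any event")
    res = _ll_logrank(da, db, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def elimination_fraction(
    records, side: str | None = None, horizon: int = 1
) -> tuple[float, int, int]:
    """Fraction of newly formed trees eliminated within ``horizon`` frames.

    Returns ``(fraction, k, n)`` with k the number of uncensored records
    with lifetime <= horizon and n the number of records considered.
    """
    if side is not None:
        records = [r for r in records if r.side == side]
    n = len(records)
    if n == 0:
        raise SurvivalError("no records for the requested side/window")
    k = sum(1 for r in records if (not r.censored) and r.lifetime <= horizon)
    return k / n, k, n


def classify_fate(record: SurvivalRecord) -> str:
    """surviving/eliminated x inside/outside fate class of one tree."""
    stem = "surviving" if record.censored else "eliminated"
    side = "in" if record.side == "inner" else "out"
    return f"{stem}_{side}"


def length_by_survival(records, lengths: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM tree length per (fate class, frames survived).

    ``lengths`` is indexed like the presence matrix (neuron_id, tree_uid,
    side) with one column per session holding the tree's total length (µm;
    NaN where unknown or absent).  Each tree contributes its length at each
    session it survived: the cell keyed (class, k) averages lengths of
    trees of that class at their k-th present session.  Missing lengths at
    a present session are skipped with a warning flag in the output.
    """
    rows = []
    for r in records:
        key = (r.neuron_id, r.tree_uid, r.side)
        if key not in lengths.index:
            continue
        vals = lengths.loc[key]
        present = vals.dropna()
        for k, (_, val) in enumerate(present.items(), start=1):
            if k > r.lifetime:
                break
            rows.append(
                {"fate": classify_fate(r), "frames_survived": k, "length": val}
            )
    if not rows:
        return pd.DataFrame(columns=["fate", "frames_survived", "mean", "sem", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["fate", "frames_survived"])["length"]
        .agg(mean="mean", sem="sem", n="count")
        .reset_index()
    )
    return out


def turnover_counts(
    pm: PresenceMatrix, window: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Per-neuron counts of newly formed and eliminated trees in a window.

    A formation at session s needs an observed absent cell at s-1; an
    elimination at session s needs presence at s-1 and an observed absent
    cell at s.  Counts are split by side.  Window bounds the session at
    which the event is scored (inclusive).
    """
    sessions = pm.sessions
    if window is None:
        window = (sessions[0], sessions[-1])
    lo, hi = sessions.index(window[0]), sessions.index(window[1])
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for (nid, uid, side), row in pm.table.iterrows():
        cells = row.to_numpy()
        key = (nid, side)
        c = counts.setdefault(key, {"formed": 0, "eliminated": 0})
        for s in range(1, len(sessions)):
            if cells[s] == "P" and cells[s - 1] == "A" and lo <= s <= hi:
                c["formed"] += 1
            if cells[s] == "A" and cells[s - 1] == "P" and lo <= s <= hi:
                c["eliminated"] += 1
    if not counts:
        return pd.DataFrame(columns=["neuron_id", "side", "formed", "eliminated"])
    out = pd.DataFrame(
        [
            {"neuron_id": nid, "side": side, **c}
            for (nid, side), c in counts.items()
        ]
    )
    return out.sort_values(["neuron_id", "side"]).reset_index(drop=True)
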