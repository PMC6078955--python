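"""Session-to-session alignment and identity tracking.

Imaging orientation drifts between sessions because the pup is detached
from the stage; the drift is corrected by a rotation-only least-squares
fit on matched soma centroids (translation is absorbed by centroid
subtraction).  Neuron identities are then carried across sessions by
mutual-nearest-neighbour soma matching, and dendritic-tree identities by
mutual-nearest origin matching after soma centering — a tree whose origin
sits in the same position in time-sequential images is the same tree.

The end product is a :class:`PresenceMatrix`: tree identity x session,
with cells present / absent / unknown, the substrate of all turnover and
survival analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .morphometry import TracedNeuron

__all__ = [
    "AlignmentResult",
    "PresenceMatrix",
    "RegistrationError",
    "AmbiguousChainError",
    "estimate_rotation",
    "match_neuron_identities",
    "match_tree_identities",
    "build_presence_matrix",
]


class RegistrationError(ValueError):
    pass


class AmbiguousChainError(RegistrationError):
    """Two distinct tracks claim the same tree in one session."""


@dataclass(frozen=True)
class AlignmentResult:
    """Rotation-only rigid alignment of one session onto another."""

    theta_deg: float              # in (-180, 180]
    pivot: np.ndarray             # (2,) source centroid, µm
    target_pivot: np.ndarray      # (2,) target centroid, µm
    residual_rmse: float          # µm

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map source-frame points into the target frame."""
        th = math.radians(self.theta_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        p = np.asarray(points, float)
        return (p - self.pivot) @ rot.T + self.target_pivot


def estimate_rotation(
    points_a: np.ndarray, points_b: np.ndarray
) -> AlignmentResult:
    """Least-squares rotation angle between two matched 2-D point sets.

    Solves ``theta = argmin sum ||R(theta)(a_i - abar) - (b_i - bbar)||^2``
    in closed form: ``theta = atan2(sum a' x b', sum a' . b')`` on the
    centered points.  Exact for noiseless rotations; with isotropic noise
    the residual RMSE scales with the noise SD.
    """
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise RegistrationError("matched (n, 2) point arrays required")
    if len(a) < 2:
        raise RegistrationError("need >= 2 matched points")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if np.allclose(ac, 0) or np.allclose(bc, 0):
        raise RegistrationError("all points coincident: rotation undefined")
    dot = float((ac * bc).sum())
    cross = float((ac[:, 0] * bc[:, 1] - ac[:, 1] * bc[:, 0]).sum())
    theta = math.degrees(math.atan2(cross, dot))
    if theta <= -180.0:
        theta += 360.0
    result = AlignmentResult(
        theta_deg=theta,
        pivot=a.mean(axis=0),
        target_pivot=b.mean(axis=0),
        residual_rmse=0.0,
    )
    resid = result.apply(a) - b
    rmse = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return AlignmentResult(theta, result.pivot, result.target_pivot, rmse)


def _mutual_nearest(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    ids_a: Sequence,
    ids_b: Sequence,
    radius: float,
) -> list[tuple]:
    """Greedy mutual-nearest pairing within ``radius``.

    Globally closest pair first; distance ties broken by the smaller id
    pair so the result is deterministic.
    """
    if len(pos_a) == 0 or len(pos_b) == 0:
        return []
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    cand = [
        (d[i, j], str(ids_a[i]), str(ids_b[j]), i, j)
        for i in range(len(ids_a))
        for j in range(len(ids_b))
        if d[i, j] <= radius
    ]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((ids_a[i], ids_b[j]))
    return pairs


def match_neuron_identities(
    session_a: Sequence[TracedNeuron],
    session_b: Sequence[TracedNeuron],
    radius: float = 30.0,
    alignment: AlignmentResult | None = None,
) -> dict:
    """Match somata across two (aligned) sessions.

    Mutual-nearest-neighbour matching of soma centers within ``radius``
    (µm, default 30).  ``alignment`` maps session-a coordinates into the
    session-b frame first.  Returns pairs plus the unmatched ids on each
    side.
    """
    pos_a = np.array([n.soma_center[:2] for n in session_a], float).reshape(-1, 2)
    pos_b = np.array([n.soma_center[:2] for n in session_b], float).reshape(-1, 2)
    if alignment is not None and len(pos_a):
        pos_a = alignment.apply(pos_a)
    ids_a = [n.neuron_id for n in session_a]
    ids_b = [n.neuron_id for n in session_b]
    pairs = _mutual_nearest(pos_a, pos_b, ids_a, ids_b, radius)
    matched_a = {a for a, _ in pairs}
    matched_b = {b for _, b in pairs}
    return {
        "pairs": pairs,
        "unmatched_a": [i for i in ids_a if i not in matched_a],
        "unmatched_b": [i for i in ids_b if i not in matched_b],
    }


def match_tree_identities(
    neuron_t: TracedNeuron,
    neuron_t1: TracedNeuron,
    tol: float = 5.0,
) -> dict:
    """Match BD-tree origins of the same neuron across two sessions.

    Origins are expressed relative to the soma center (which absorbs
    translation and slow brain growth), then paired mutual-nearest within
    ``tol`` µm of 3-D distance.  Trees of ``neuron_t`` left unmatched were eliminated;
    trees of ``neuron_t1`` left unmatched were newly formed.
    """
    trees_t = neuron_t.bd_trees
    trees_t1 = neuron_t1.bd_trees
    pos_t = np.array(
        [t.origin - neuron_t.soma_center for t in trees_t], float
    ).reshape(-1, 3)
    pos_t1 = np.array(
        [t.origin - neuron_t1.soma_center for t in trees_t1], float
    ).reshape(-1, 3)
    ids_t = [t.tree_id for t in trees_t]
    ids_t1 = [t.tree_id for t in trees_t1]
    pairs = _mutual_nearest(pos_t, pos_t1, ids_t, ids_t1, tol)
    matched_t = {a for a, _ in pairs}
    matched_t1 = {b for _, b in pairs}
    return {
        "mapping": pairs,
        "eliminated": [i for i in ids_t if i not in matched_t],
        "births": [i for i in ids_t1 if i not in matched_t1],
    }


@dataclass
class PresenceMatrix:
    """Tree identity x session presence table.

    ``table`` is a DataFrame indexed by ``(neuron_id, tree_uid, side)``
    with one column per session holding ``"P"`` (present), ``"A"``
    (absent) or ``"U"`` (unknown: the image was not acquired).
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def sessions(self) -> list[str]:
        return list(self.table.columns)

    def lifetimes(self) -> pd.Series:
        """Consecutive present sessions per tree, from first appearance."""
        return self.table.apply(lambda row: int((row == "P").sum()), axis=1)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, index_col=[0, 1, 2])
        return cls(table=df)


def build_presence_matrix(
    dataset: Mapping[str, Sequence[TracedNeuron]],
    tol: float = 5.0,
    bridge_gaps: bool = True,
    missing: Mapping[str, Sequence[str]] | None = None,
    barrel_map=None,
) -> PresenceMatrix:
    """Chain tree identities through a longitudinal dataset.

    ``dataset`` maps session id (in chronological order of insertion) to
    the neurons traced at that session.  ``missing`` maps neuron id to
    sessions at which that neuron's image was not acquired (cells marked
    unknown).  With ``bridge_gaps`` a track survives a single unknown
    session when origins match across the gap.

    Tree identities (``tree_uid``) are ``{birth_session}:{tree_id}`` of the
    first appearance; side labels are taken from the tree ids produced by
    the matching caller if encoded, else left empty (the survival module
    re-derives sides from geometry when needed).
    """
    sessions = list(dataset.keys())
    missing = {k: set(v) for k, v in (missing or {}).items()}

    # group neurons by id per session
    by_neuron: dict[str, dict[str, TracedNeuron]] = {}
    for s in sessions:
        for neu in dataset[s]:
            by_neuron.setdefault(neu.neuron_id, {})[s] = neu

    rows: dict[tuple, dict[str, str]] = {}

    for nid, per_session in by_neuron.items():
        miss = missing.get(nid, set())
        # track: uid -> (last_seen_session_index, tree_id_at_last_seen)
        active: dict[str, tuple[int, str]] = {}
        uid_of: dict[tuple[int, str], str] = {}  # (session_idx, tree_id) -> uid
        for si, s in enumerate(sessions):
            if s in miss or s not in per_session:
                continue
            neu = per_session[s]
            # candidate previous session for each active track
            prev_trees: list[str] = []
            prev_neu_idx: dict[str, int] = {}
            for uid, (last_si, last_tid) in active.items():
                gap = si - last_si
                limit = 2 if bridge_gaps else 1
                if gap <= limit:
                    # allow bridging only when intervening sessions unknown
                    inter = sessions[last_si + 1 : si]
                    if gap == 1 or all(
                        t in miss or t not in per_session for t in inter
                    ):
                        prev_trees.append(uid)
                        prev_neu_idx[uid] = last_si
            # positions of active tracks (origin at last seen, soma-relative)
            pos_prev = []
            for uid in prev_trees:
                last_si, last_tid = active[uid]
                pneu = per_session[sessions[last_si]]
                tr = next(t for t in pneu.bd_trees if t.tree_id == last_tid)
                pos_prev.append(tr.origin - pneu.soma_center)
            pos_prev = np.array(pos_prev, float).reshape(-1, 3)
            cur_trees = neu.bd_trees
            pos_cur = np.array(
                [t.origin - neu.soma_center for t in cur_trees], float
            ).reshape(-1, 3)
            cur_ids = [t.tree_id for t in cur_trees]
            pairs = _mutual_nearest(pos_prev, pos_cur, prev_trees, cur_ids, tol)
            matched_uid = {}
            for uid, tid in pairs:
                if tid in matched_uid.values():
                    raise AmbiguousChainError(
                        f"neuron {nid}: tree {tid} at {s} claimed twice"
                    )
                matched_uid[uid] = tid
            # update tracks
            for uid, tid in matched_uid.items():
                active[uid] = (si, tid)
                uid_of[(si, tid)] = uid
            matched_tids = set(matched_uid.values())
            for t in cur_trees:
                if t.tree_id not in matched_tids:
                    uid = f"{s}:{t.tree_id}"
                    active[uid] = (si, t.tree_id)
                    uid_of[(si, t.tree_id)] = uid
            # a candidate track unmatched at an observed session is dead;
            # a non-candidate track has exceeded the bridgeable gap
            dead = [
                uid
                for uid in list(active)
                if active[uid][0] < si
                and (uid in prev_trees or si - active[uid][0] >= (2 if bridge_gaps else 1))
            ]
            for uid in dead:
                del active[uid]

        # build rows: for each uid collect presence over sessions
        seen: dict[str, set[int]] = {}
        for (si, tid), uid in uid_of.items():
            seen.setdefault(uid, set()).add(si)
        for uid, present_idx in seen.items():
            row = {}
            for si, s in enumerate(sessions):
                if s in miss or s not in per_session:
                    row[s] = "U"
                elif si in present_idx:
                    row[s] = "P"
                else:
                    row[s] = "A"
            # present cells between first and last sighting across a bridged
            # unknown session remain U (image truly not acquired)
            side = ""
            if barrel_map is not None:
                from .morphometry import inside_outside_boundary, tree_side

                birth_si = min(present_idx)
                birth_s = sessions[birth_si]
                bneu = per_session[birth_s]
                birth_tid = next(
                    tid for (sj, tid), u in uid_of.items()
                    if u == uid and sj == birth_si
                )
                tr = next(t for t in bneu.bd_trees if t.tree_id == birth_tid)
                boundary = inside_outside_boundary(bneu, barrel_map)
                side = tree_side(tr, boundary)
            rows[(nid, uid, side)] = row

    if rows:
        table = pd.DataFrame.from_dict(rows, orient="index", columns=sessions)
        table.index = pd.MultiIndex.from_tuples(
            table.index, names=["neuron_id", "tree_uid", "side"]
        )
    else:
        table = pd.DataFrame(
            columns=sessions,
            index=pd.MultiIndex.from_tuples([], names=["neuron_id", "tree_uid", "side"]),
        )
    return PresenceMatrix(
        table=table,
        provenance={"tol_um": tol, "bridge_gaps": bridge_gaps},
    )
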