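"""Synthetic longitudinal morphology datasets and calcium movies.

The generators emulate the study conditions every downstream stage needs:

* an 8-session imaging schedule (P3_L .. P5_L every 8 h, plus P6_L),
* neuron classes — barrel-edge spiny stellate (eSS, soma within 12.5 µm of
  the barrel boundary, side-asymmetric tree turnover), barrel-center SS
  (cSS), infraorbital-nerve-cut SS (iSS, cSS-like low turnover) and
  barrel-edge star pyramid (eSP, unbiased),
* basal-dendrite tree birth/death: Poisson births per side per 8-h frame,
  one-frame elimination probability p1 (defaults 0.31 inner / 0.82 outer
  for eSS), a later per-frame hazard, and linear growth of survivors with
  side-specific slope,
* apical-dendrite trajectories: Group 1 (gradual retraction with variable
  onset, or AD absent) vs Group 2 (continuous extension),
* calcium movies: control "patchwork" events confined to single barrels
  vs ION-cut events with random centers and >= 2.5 barrel-diameter spatial
  spread, 1-frame rise, exponential decay, Gaussian noise, and a
  guaranteed quiescent prefix for the F0 baseline.

Every generator takes a :class:`numpy.random.Generator` (or an integer
seed) and is bit-reproducible for a fixed seed and config.  Each run emits
a ground-truth event log so tracking, survival and zone-detection
pipelines can be tested against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .calcium import CalciumMovie
from .morphometry import Barrel, BarrelMap, DendriticTree, TracedNeuron

__all__ = [
    "SimConfig",
    "TreeProcessParams",
    "CalciumSimParams",
    "LongitudinalDataset",
    "DEFAULT_SESSIONS",
    "gen_barrel_map",
    "gen_longitudinal_neurons",
    "gen_calcium_movie",
]

DEFAULT_SESSIONS = ["P3_L", "P4_E", "P4_M", "P4_L", "P5_E", "P5_M", "P5_L", "P6_L"]

_MIN_SEG = 6.0        # µm, keeps every emitted segment above the 5 µm twig rule
_SOMA_RADIUS = 7.0    # µm
_TIP_LENGTH_UM = 26.0  # µm of added tree length per extra tip


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeProcessParams:
    """Birth–death–growth parameters for one neuron class.

    Newly formed trees die after their first frame with probability
    ``p1_*`` and on each later frame with hazard ``hazard_*``; trees
    already present at the first session are established and carry the
    lower ``hazard_init_*``.  Survivors gain ``slope_*`` µm per frame.
    """

    lambda_in: float          # tree births / frame, barrel-center side
    lambda_out: float         # tree births / frame, far side
    p1_in: float              # one-frame elimination probability, inner
    p1_out: float             # one-frame elimination probability, outer
    hazard_in: float          # per-frame death probability after frame 1
    hazard_out: float
    hazard_init_in: float     # per-frame death probability, initial trees
    hazard_init_out: float
    slope_in: float           # µm growth per surviving frame
    slope_out: float
    init_trees_in: float      # mean initial tree count per side (Poisson, min 1)
    init_trees_out: float


#: eSS defaults: one-frame elimination 0.31/0.82 (inner/outer); birth rates
#: from 16 inner / 22 outer new trees per 8 neurons per 6 frames; initial
#: counts 3.5 inner / 1.5 outer per neuron; inner winners grow steeply,
#: outer trees stay short.
_ESS = TreeProcessParams(
    lambda_in=0.33, lambda_out=0.46,
    p1_in=0.31, p1_out=0.82,
    hazard_in=0.10, hazard_out=0.15,
    hazard_init_in=0.02, hazard_init_out=0.12,
    slope_in=30.0, slope_out=5.0,
    init_trees_in=3.5, init_trees_out=1.5,
)
#: cSS / iSS: suppressed turnover, symmetric moderate growth.
_CSS = TreeProcessParams(
    lambda_in=0.15, lambda_out=0.15,
    p1_in=0.10, p1_out=0.10,
    hazard_in=0.03, hazard_out=0.03,
    hazard_init_in=0.015, hazard_init_out=0.015,
    slope_in=19.5, slope_out=19.5,
    init_trees_in=2.5, init_trees_out=2.5,
)
#: eSP: unbiased, mild turnover.
_ESP = TreeProcessParams(
    lambda_in=0.15, lambda_out=0.15,
    p1_in=0.30, p1_out=0.30,
    hazard_in=0.05, hazard_out=0.05,
    hazard_init_in=0.03, hazard_init_out=0.03,
    slope_in=22.5, slope_out=22.5,
    init_trees_in=2.5, init_trees_out=2.5,
)

_CLASS_PARAMS = {"eSS": _ESS, "cSS": _CSS, "iSS": _CSS, "eSP": _ESP}


@dataclass(frozen=True)
class CalciumSimParams:
    """Parameters of the synthetic spontaneous-activity movie."""

    n_frames: int = 900           # 15 min at 1 Hz
    size_px: int = 256
    um_per_px: float = 2.0
    hz: float = 1.0
    quiet_frames: int = 60        # guaranteed event-free prefix for F0
    event_rate: float = 0.08      # events / frame over the whole field
    amplitude: float = 2.0        # peak ΔF/F of an event plateau
    tau_s: float = 1.5            # GCaMP-like exponential decay constant
    noise_sd: float = 0.02        # Gaussian noise SD as fraction of baseline
    baseline: float = 100.0
    ion_spread_mult: float = 2.5  # min ION-cut event extent / barrel diameter
    edge_sigma_px: float = 2.0    # softness of the event plateau edge


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the longitudinal morphology generator."""

    n_neurons: int = 20
    class_mix: dict = field(
        default_factory=lambda: {"eSS": 0.5, "cSS": 0.26, "iSS": 0.0, "eSP": 0.24}
    )
    sessions: tuple = tuple(DEFAULT_SESSIONS)
    init_length_mean: float = 65.0   # µm, initial tree length (truncated > 5)
    init_length_sd: float = 36.0
    new_tree_length: tuple = (6.0, 18.0)   # uniform range for newborn trees
    growth_noise_sd: float = 0.15          # multiplicative, per increment
    ad_init_mean: float = 165.0
    ad_init_sd: float = 35.0
    ad_absent_prob: float = 0.03           # Group 1 neurons lacking AD at start
    ad_retract_rate: float = 40.0          # µm / frame once retraction starts
    ad_extend_rate: float = 15.0           # µm / frame, Group 2
    barrel_rows: int = 2
    barrel_cols: int = 2
    barrel_diameter: float = 150.0
    septum: float = 30.0
    calcium: CalciumSimParams = field(default_factory=CalciumSimParams)
    #: per-class TreeProcessParams overrides (None -> built-in defaults)
    class_params: dict | None = None

    def params_for(self, klass: str) -> TreeProcessParams:
        if self.class_params and klass in self.class_params:
            return self.class_params[klass]
        return _CLASS_PARAMS[klass]

    def validate(self) -> None:
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class mix sums to {total}, expected 1")
        for p in [self.params_for(k) for k in self.class_mix]:
            for v in (p.p1_in, p.p1_out, p.hazard_in, p.hazard_out,
                      p.hazard_init_in, p.hazard_init_out):
                if not 0 <= v <= 1:
                    raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# barrel map
# ---------------------------------------------------------------------------


def gen_barrel_map(
    rows: int = 2,
    cols: int = 2,
    barrel_diameter: float = 150.0,
    septum: float = 30.0,
    seed=0,
    n_vertices: int = 28,
) -> BarrelMap:
    """Regular grid of near-circular barrels.

    Barrel centers sit on a grid with pitch ``diameter + septum``; each
    boundary is a polygon with mild radial irregularity so edge geometry
    is exercised without self-intersection.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    rng = _rng(seed)
    pitch = barrel_diameter + septum
    r0 = barrel_diameter / 2
    barrels = []
    for i in range(rows):
        for j in range(cols):
            cx = (j + 0.5) * pitch
            cy = (i + 0.5) * pitch
            ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
            wobble = 1.0 + 0.04 * np.sin(3 * ang + rng.uniform(0, 2 * np.pi))
            ring = np.column_stack(
                [cx + r0 * wobble * np.cos(ang), cy + r0 * wobble * np.sin(ang)]
            )
            barrels.append(
                Barrel(
                    barrel_id=f"b{i}{j}",
                    center=np.array([cx, cy]),
                    boundary=ring,
                )
            )
    return BarrelMap(barrels=barrels)


# ---------------------------------------------------------------------------
# arbor geometry
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rot_xy(v: np.ndarray, deg: float) -> np.ndarray:
    th = math.radians(deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


def _grow_path(
    nodes: list, parents: list, start_idx: int, direction: np.ndarray,
    length: float, rng: np.random.Generator,
) -> int:
    """Append a tortuous path of exact arc length; returns tip node index."""
    n_steps = max(2, int(length // 9) + 1)
    step = length / n_steps
    d = direction.copy()
    idx = start_idx
    for _ in range(n_steps):
        d = _rot_xy(d, rng.normal(0, 7.0))
        d = _unit(d + np.array([0, 0, rng.normal(0, 0.05)]))
        new_pt = nodes[idx] + d * step
        nodes.append(new_pt)
        parents.append(idx)
        idx = len(nodes) - 1
    return idx


def _grow_subtree(
    nodes: list, parents: list, start_idx: int, direction: np.ndarray,
    length: float, tips: int, rng: np.random.Generator,
) -> None:
    if tips <= 1 or length < 3 * _MIN_SEG:
        _grow_path(nodes, parents, start_idx, direction, length, rng)
        return
    # trunk, then two daughter subtrees splitting the tips
    min_rest = _MIN_SEG * (2 * tips - 2)
    trunk = min(max(_MIN_SEG, 0.3 * length), max(_MIN_SEG, length - min_rest))
    branch_idx = _grow_path(nodes, parents, start_idx, direction, trunk, rng)
    rest = length - trunk
    t1 = tips // 2
    t2 = tips - t1
    frac = t1 / tips * rng.uniform(0.8, 1.2)
    l1 = np.clip(rest * frac, _MIN_SEG * max(1, 2 * t1 - 1), rest - _MIN_SEG * max(1, 2 * t2 - 1))
    l2 = rest - l1
    spread = rng.uniform(22, 42)
    _grow_subtree(nodes, parents, branch_idx, _rot_xy(direction, +spread), l1, t1, rng)
    _grow_subtree(nodes, parents, branch_idx, _rot_xy(direction, -spread), l2, t2, rng)


def _build_tree(
    tree_id: str,
    soma_center: np.ndarray,
    angle_deg: float,
    toward_center: np.ndarray,   # 2-D unit vector, 0° reference
    length: float,
    rng: np.random.Generator,
    phi_deg: float = 0.0,
    kind: str = "BD",
) -> DendriticTree:
    """Build a tortuous arbor of exact total length rooted on the soma.

    ``angle_deg`` positions the origin on the soma relative to the
    barrel-center direction (0° = toward the barrel center); ``phi_deg``
    tilts the origin out of the tangential plane.  The arbor itself grows
    radially outward in the plane.  Tip count scales with length (one
    extra tip per 26 µm).
    """
    ref = math.degrees(math.atan2(toward_center[1], toward_center[0]))
    origin = soma_center + _origin_offset(ref + angle_deg, phi_deg)
    th = math.radians(ref + angle_deg)
    radial = np.array([math.cos(th), math.sin(th), 0.0])
    tips = 1 + int(length // _TIP_LENGTH_UM)
    tips = min(tips, max(1, int((length - _MIN_SEG) // (2 * _MIN_SEG))))
    nodes = [origin.copy()]
    parents = [-1]
    _grow_subtree(nodes, parents, 0, radial, length, tips, rng)
    return DendriticTree(
        tree_id=tree_id,
        nodes=np.array(nodes),
        parents=np.array(parents),
        kind=kind,
    )


def _build_axial_tree(
    tree_id: str, soma_center: np.ndarray, length: float,
    rng: np.random.Generator, up: bool, kind: str,
) -> DendriticTree:
    """Near-vertical unbranched process (apical dendrite or axon)."""
    sign = 1.0 if up else -1.0
    origin = soma_center + np.array([0.0, 0.0, sign * _SOMA_RADIUS])
    n_steps = max(2, int(length // 12) + 1)
    step = length / n_steps
    nodes = [origin.copy()]
    parents = [-1]
    d = np.array([0.0, 0.0, sign])
    idx = 0
    for _ in range(n_steps):
        d = _unit(d + np.array([rng.normal(0, 0.06), rng.normal(0, 0.06), 0]))
        nodes.append(nodes[idx] + d * step)
        parents.append(idx)
        idx = len(nodes) - 1
    return DendriticTree(
        tree_id=tree_id, nodes=np.array(nodes), parents=np.array(parents), kind=kind
    )


# ---------------------------------------------------------------------------
# longitudinal morphology generator
# ---------------------------------------------------------------------------


@dataclass
class LongitudinalDataset:
    """Generator output: per-session traced neurons plus ground truth."""

    dataset: dict                 # session_id -> list[TracedNeuron]
    barrel_map: BarrelMap
    truth: dict                   # event log (see gen_longitudinal_neurons)
    config: SimConfig

    def lengths_table(self) -> pd.DataFrame:
        """Tree length per session, indexed like the presence matrix."""
        rows = {}
        for uid, info in self.truth["trees"].items():
            key = (info["neuron_id"], uid, info["side"])
            rows[key] = {
                s: info["lengths"].get(s, np.nan) for s in self.config.sessions
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index = pd.MultiIndex.from_tuples(
            df.index, names=["neuron_id", "tree_uid", "side"]
        )
        return df[list(self.config.sessions)]


def _place_soma(
    klass: str, barrel: Barrel, rng: np.random.Generator
) -> np.ndarray:
    """Soma position per class: eSS/eSP hug the boundary, cSS/iSS the center."""
    center = np.array([barrel.center[0], barrel.center[1], 0.0])
    ring = barrel.boundary
    if klass in ("eSS", "eSP"):
        v = ring[rng.integers(len(ring))] - barrel.center
        r = np.linalg.norm(v)
        # 6-10 µm inside the boundary: within the 12.5 µm edge band
        inset = rng.uniform(6.0, 10.0)
        pos = barrel.center + v / r * (r - inset)
        return np.array([pos[0], pos[1], 0.0])
    # center classes: small offset so the soma->center direction is defined
    ang = rng.uniform(0, 2 * np.pi)
    off = rng.uniform(8.0, 18.0)
    return center + np.array([off * math.cos(ang), off * math.sin(ang), 0.0])


def _origin_offset(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Origin position on the soma sphere, relative to the soma center.

    ``theta`` is the azimuth in the tangential plane relative to the
    barrel-center direction (applied by the caller); ``phi`` tilts the
    origin out of the plane.
    """
    th, ph = math.radians(theta_deg), math.radians(phi_deg)
    return _SOMA_RADIUS * np.array(
        [math.cos(ph) * math.cos(th), math.cos(ph) * math.sin(th), math.sin(ph)]
    )


def _sample_origin(
    side: str,
    rng: np.random.Generator,
    live: list[tuple[float, float]],
    dead: list[tuple[float, float]],
) -> tuple[float, float]:
    """(azimuth, tilt) on the soma sphere for a newborn tree's origin.

    Live origins only need a small clearance (coincident roots are
    geometrically degenerate); origins vacated by a recent elimination
    need more than the matching tolerance, otherwise the tracker would
    chain the newborn to the dead tree's identity — which no human tracer
    would accept either.
    """
    lo, hi = (-89.0, 89.0) if side == "inner" else (91.0, 269.0)
    dead_sep = 5.5   # µm, > matching tolerance
    live_sep = 2.0   # µm

    live_pos = [_origin_offset(t, p) for (t, p) in live]
    dead_pos = [_origin_offset(t, p) for (t, p) in dead]
    theta, phi = rng.uniform(lo, hi), rng.uniform(-50.0, 50.0)
    for _ in range(120):
        theta = rng.uniform(lo, hi)
        if theta > 180.0:
            theta -= 360.0
        phi = rng.uniform(-50.0, 50.0)
        pos = _origin_offset(theta, phi)
        if all(np.linalg.norm(pos - q) >= live_sep for q in live_pos) and all(
            np.linalg.norm(pos - q) >= dead_sep for q in dead_pos
        ):
            return theta, phi
    return theta, phi  # crowded soma: accept the last draw


def gen_longitudinal_neurons(
    config: SimConfig | None = None, seed=0
) -> LongitudinalDataset:
    """Simulate a longitudinal traced-neuron dataset with ground truth.

    Per neuron and 8-h frame, new trees are born Poisson(lambda_side); a
    newborn dies after its first frame with probability p1_side, and each
    later frame with the class hazard; survivors grow linearly with
    side-specific slope and multiplicative noise.  Tree origins are fixed
    on the soma for life, so origin matching can recover identity exactly.

    The ground-truth log records, per tree: neuron, side, birth/death
    session indices (death None if still present at the end) and length
    per session; plus each neuron's class and AD-length trajectory.
    """
    config = config or SimConfig()
    config.validate()
    rng = _rng(seed)
    barrel_map = gen_barrel_map(
        config.barrel_rows, config.barrel_cols,
        config.barrel_diameter, config.septum,
        seed=rng.integers(2**31),
    )
    sessions = list(config.sessions)
    n_s = len(sessions)

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    dataset: dict[str, list[TracedNeuron]] = {s: [] for s in sessions}
    truth: dict = {"neurons": {}, "trees": {}, "births": [], "deaths": []}

    for ni in range(config.n_neurons):
        nid = f"n{ni:03d}"
        klass = classes[rng.choice(len(classes), p=probs)]
        params = config.params_for(klass)
        barrel = barrel_map.barrels[rng.integers(len(barrel_map.barrels))]
        soma = _place_soma(klass, barrel, rng)
        toward = _unit(np.asarray(barrel.center, float) - soma[:2])

        # --- AD trajectory ---
        group = "Group2" if klass == "eSP" else "Group1"
        ad_lengths = np.zeros(n_s)
        if group == "Group1" and rng.uniform() < config.ad_absent_prob:
            pass  # no AD at any session
        else:
            l0 = float(np.clip(rng.normal(config.ad_init_mean, config.ad_init_sd),
                               29.0, 228.0))
            if group == "Group1":
                onset = int(rng.integers(0, 5))  # retraction start frame
                ln = l0
                for s in range(n_s):
                    ad_lengths[s] = max(0.0, ln)
                    ln = ln + 10.0 if s < onset else ln - config.ad_retract_rate
            else:
                for s in range(n_s):
                    ad_lengths[s] = l0 + config.ad_extend_rate * s
        truth["neurons"][nid] = {
            "class": klass, "group": group,
            "ad_lengths": ad_lengths.tolist(),
            "home_barrel": barrel.barrel_id,
        }

        # --- BD tree birth-death process ---
        # live trees: uid -> dict(side, angle, length, born, age)
        live: dict[str, dict] = {}
        recent_dead: list[tuple[float, float, int]] = []  # (angle, phi, death idx)
        counter = 0

        def new_uid():
            nonlocal counter
            counter += 1
            return f"{nid}-t{counter:03d}"

        def spawn(side: str, session_idx: int, length: float):
            live_or = [(t["angle"], t["phi"]) for t in live.values()]
            dead_or = [
                (a, p) for (a, p, died) in recent_dead if session_idx - died <= 2
            ]
            ang, phi = _sample_origin(side, rng, live_or, dead_or)
            uid = new_uid()
            live[uid] = {
                "side": side, "angle": ang, "phi": phi, "length": length,
                "born": session_idx, "age": 0,
            }
            truth["trees"][uid] = {
                "neuron_id": nid, "side": side, "birth": session_idx,
                "death": None, "lengths": {},
            }
            if session_idx > 0:
                truth["births"].append(
                    {"neuron_id": nid, "tree_uid": uid, "side": side,
                     "session": sessions[session_idx]}
                )

        # initial trees (at least one inner tree so every neuron has BDs)
        for side, mean_n in (("inner", params.init_trees_in),
                             ("outer", params.init_trees_out)):
            k = int(rng.poisson(mean_n)) if mean_n > 0 else 0
            if side == "inner":
                k = max(1, k)
            for _ in range(k):
                ln = -1.0
                while ln <= 5.0:
                    ln = rng.normal(config.init_length_mean, config.init_length_sd)
                spawn(side, 0, float(ln))

        for si in range(n_s):
            if si > 0:
                # deaths between si-1 and si
                doomed = []
                for uid, t in live.items():
                    inner = t["side"] == "inner"
                    if t["born"] == 0:
                        p_die = (params.hazard_init_in if inner
                                 else params.hazard_init_out)
                    elif t["age"] == 0:
                        p_die = params.p1_in if inner else params.p1_out
                    else:
                        p_die = params.hazard_in if inner else params.hazard_out
                    if rng.uniform() < p_die:
                        doomed.append(uid)
                for uid in doomed:
                    truth["trees"][uid]["death"] = si
                    truth["deaths"].append(
                        {"neuron_id": nid, "tree_uid": uid,
                         "side": live[uid]["side"], "session": sessions[si]}
                    )
                    recent_dead.append(
                        (live[uid]["angle"], live[uid]["phi"], si)
                    )
                    del live[uid]
                # growth of survivors
                for t in live.values():
                    slope = (params.slope_in if t["side"] == "inner"
                             else params.slope_out)
                    inc = slope * (1.0 + rng.normal(0, config.growth_noise_sd))
                    t["length"] = max(5.5, t["length"] + inc)
                    t["age"] += 1
                # births at si
                for side, lam in (("inner", params.lambda_in),
                                  ("outer", params.lambda_out)):
                    for _ in range(rng.poisson(lam)):
                        spawn(side, si, float(rng.uniform(*config.new_tree_length)))

            # --- emit traced neuron for this session ---
            trees = []
            for uid, t in live.items():
                truth["trees"][uid]["lengths"][sessions[si]] = t["length"]
                trees.append(
                    _build_tree(
                        tree_id=uid, soma_center=soma, angle_deg=t["angle"],
                        phi_deg=t["phi"], toward_center=toward,
                        length=t["length"], rng=rng,
                    )
                )
            if ad_lengths[si] > 0:
                trees.append(
                    _build_axial_tree(f"{nid}-AD", soma, ad_lengths[si],
                                      rng, up=True, kind="AD")
                )
            trees.append(
                _build_axial_tree(f"{nid}-ax", soma, 80.0, rng, up=False,
                                  kind="axon")
            )
            dataset[sessions[si]].append(
                TracedNeuron(
                    neuron_id=nid, session_id=sessions[si],
                    soma_center=soma.copy(), trees=trees,
                    home_barrel_id=barrel.barrel_id,
                )
            )

    return LongitudinalDataset(
        dataset=dataset, barrel_map=barrel_map, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# calcium movie generator
# ---------------------------------------------------------------------------


def _plateau_mask(
    shape: tuple[int, int], inside_fn, edge_sigma_px: float
) -> np.ndarray:
    """Soft-edged indicator in [0, 1]: 0.5 exactly at the region boundary."""
    ind = inside_fn().astype(float)
    if edge_sigma_px > 0:
        ind = ndimage.gaussian_filter(ind, sigma=edge_sigma_px)
    return ind


def gen_calcium_movie(
    config: SimConfig | None = None,
    regime: str = "control",
    seed=0,
    barrel_map: BarrelMap | None = None,
) -> tuple[CalciumMovie, pd.DataFrame]:
    """Synthetic spontaneous-activity movie plus a ground-truth event table.

    Control regime: each event activates exactly one barrel's interior (a
    smooth-edged plateau at the configured amplitude).  ION-cut regime:
    events have random centers and elliptical extents of at least
    ``ion_spread_mult`` barrel diameters with wobbly, variable boundaries.
    Events rise in one frame and decay exponentially (tau 1.5 s); Gaussian
    noise rides on a flat baseline; the first ``quiet_frames`` frames are
    guaranteed event-free so an F0 baseline always exists.

    Returns ``(movie, events)`` where ``events`` has one row per event:
    onset frame, amplitude, regime-specific geometry (barrel id or
    center/axes) and the plateau area in µm².
    """
    config = config or SimConfig()
    if regime not in ("control", "ion_cut"):
        raise ValueError(f"unknown regime {regime!r}")
    cp = config.calcium
    rng = _rng(seed)
    n, hw = cp.n_frames, cp.size_px
    px = cp.um_per_px
    field_um = hw * px
    if barrel_map is None:
        barrel_map = gen_barrel_map(
            config.barrel_rows, config.barrel_cols,
            config.barrel_diameter, config.septum,
            seed=rng.integers(2**31),
        )
    # barrel extent must fit the field
    xmin, ymin, xmax, ymax = barrel_map.field_bbox
    if xmax > field_um or ymax > field_um:
        raise ValueError("barrel map does not fit the imaging field")

    yy, xx = np.mgrid[0:hw, 0:hw]
    xx_um = (xx + 0.5) * px
    yy_um = (yy + 0.5) * px

    # precompute control plateaus: one per barrel
    barrel_masks = {}
    for b in barrel_map.barrels:
        r_ang = np.arctan2(yy_um - b.center[1], xx_um - b.center[0])
        # radial distance of the polygon at each pixel's angle
        ring = b.boundary - b.center
        ring_ang = np.arctan2(ring[:, 1], ring[:, 0])
        ring_rad = np.linalg.norm(ring, axis=1)
        order = np.argsort(ring_ang)
        rad_at = np.interp(
            r_ang, ring_ang[order], ring_rad[order],
            period=2 * np.pi,
        )
        dist = np.hypot(xx_um - b.center[0], yy_um - b.center[1])
        barrel_masks[b.barrel_id] = _plateau_mask(
            (hw, hw), lambda: dist <= rad_at, cp.edge_sigma_px
        )

    # --- schedule events ---
    events = []
    activity = np.zeros((n, hw, hw))
    decay = np.exp(-1.0 / (cp.tau_s * cp.hz))
    kernel_len = max(1, int(np.ceil(cp.tau_s * cp.hz * 5)))
    kernel = decay ** np.arange(kernel_len)

    for t in range(cp.quiet_frames, n):
        if rng.uniform() >= cp.event_rate:
            continue
        amp = cp.amplitude * rng.uniform(0.9, 1.3)
        if regime == "control":
            b = barrel_map.barrels[rng.integers(len(barrel_map.barrels))]
            plateau = barrel_masks[b.barrel_id]
            area = float((plateau >= 0.5).sum()) * px**2
            events.append(
                {"frame": t, "regime": regime, "amplitude": amp,
                 "barrel_id": b.barrel_id, "area_um2": area,
                 "cx_um": float(b.center[0]), "cy_um": float(b.center[1])}
            )
        else:
            # random center, extent >= ion_spread_mult barrel diameters,
            # wobbly elliptical boundary
            d_um = config.barrel_diameter * rng.uniform(
                cp.ion_spread_mult, cp.ion_spread_mult * 1.3
            )
            a_um = d_um / 2 * rng.uniform(0.85, 1.2)
            b_um = d_um / 2 * rng.uniform(0.85, 1.2)
            cx = rng.uniform(0.25 * field_um, 0.75 * field_um)
            cy = rng.uniform(0.25 * field_um, 0.75 * field_um)
            phi = rng.uniform(0, np.pi)
            w_amp = rng.uniform(0.0, 0.12)
            w_ph = rng.uniform(0, 2 * np.pi)
            dx, dy = xx_um - cx, yy_um - cy
            u = dx * np.cos(phi) + dy * np.sin(phi)
            v = -dx * np.sin(phi) + dy * np.cos(phi)
            ang = np.arctan2(v, u)
            wob = 1.0 + w_amp * np.sin(3 * ang + w_ph)
            inside = (u / (a_um * wob)) ** 2 + (v / (b_um * wob)) ** 2 <= 1.0
            plateau = _plateau_mask((hw, hw), lambda: inside, cp.edge_sigma_px)
            area = float((plateau >= 0.5).sum()) * px**2
            events.append(
                {"frame": t, "regime": regime, "amplitude": amp,
                 "barrel_id": None, "area_um2": area,
                 "cx_um": float(cx), "cy_um": float(cy)}
            )
        t_end = min(n, t + kernel_len)
        activity[t:t_end] += (
            plateau[None, :, :] * (amp * kernel[: t_end - t])[:, None, None]
        )

    frames = cp.baseline * (1.0 + activity)
    if cp.noise_sd > 0:
        frames = frames + rng.normal(0, cp.noise_sd * cp.baseline, frames.shape)
    frames = np.clip(frames, 0, None)
    movie = CalciumMovie(frames=frames, um_per_px=px, hz=cp.hz)
    return movie, pd.DataFrame(events)
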