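"""Discrete-event model of dual-pathway AV-nodal conduction.

The conduction system is represented as a small undirected network: two
chains of nodes (a slow pathway, SP, and a fast pathway, FP) whose distal
ends are joined to each other and to a single coupling node (CN).  Atrial
impulses enter simultaneously at the proximal node of each chain; every
conduction through the CN produces one ventricular activation.

Each node carries a recovery-dependent refractory period and conduction
delay,

    R(g) = a_r * (r_min + delta_r * (1 - exp(-g / tau_r)))
    D(g) = a_d * (d_min + delta_d * exp(-g / tau_d))

where ``g`` is the excitation gap -- the time between an impulse's arrival
and the end of the node's previous refractory period -- and ``a_r``,
``a_d`` are dimensionless autonomic-tone scaling factors shared by all
nodes (``a_r = a_d = 1`` gives the unscaled model).  An impulse is
conducted iff its excitation gap is strictly positive (a never-activated
node always conducts); on conduction the impulse is forwarded to all
neighbours after the delay ``D(g)``.  Blocked impulses do not alter node
state.

All times are in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "FULLY_RECOVERED",
    "PathwayParams",
    "ModelParams",
    "NodeState",
    "NetworkTopology",
    "ScalingSchedule",
    "DEFAULT_CN_PARAMS",
    "refractory_period",
    "conduction_delay",
    "excitation_gap",
    "build_network",
    "simulate",
    "validate_aa_series",
]

#: Sentinel excitation gap of a node that has never been activated: the
#: tissue is treated as maximally recovered (gap -> +inf).
FULLY_RECOVERED = math.inf


@dataclass(frozen=True)
class PathwayParams:
    """Six-parameter description of one pathway's nodes (all in ms)."""

    r_min: float
    delta_r: float
    tau_r: float
    d_min: float
    delta_d: float
    tau_d: float

    def __post_init__(self) -> None:
        if not self.r_min > 0:
            raise ValueError(f"r_min must be > 0, got {self.r_min}")
        if self.delta_r < 0:
            raise ValueError(f"delta_r must be >= 0, got {self.delta_r}")
        if not self.tau_r > 0:
            raise ValueError(f"tau_r must be > 0, got {self.tau_r}")
        if self.d_min < 0:
            raise ValueError(f"d_min must be >= 0, got {self.d_min}")
        if self.delta_d < 0:
            raise ValueError(f"delta_d must be >= 0, got {self.delta_d}")
        if not self.tau_d > 0:
            raise ValueError(f"tau_d must be > 0, got {self.tau_d}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.r_min, self.delta_r, self.tau_r,
             self.d_min, self.delta_d, self.tau_d],
            dtype=np.float64,
        )

    def to_dict(self) -> dict:
        return {
            "r_min": self.r_min, "delta_r": self.delta_r, "tau_r": self.tau_r,
            "d_min": self.d_min, "delta_d": self.delta_d, "tau_d": self.tau_d,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayParams":
        return cls(**{k: float(d[k]) for k in
                      ("r_min", "delta_r", "tau_r", "d_min", "delta_d", "tau_d")})


#: Coupling-node defaults: fixed 250 ms refractory period and zero delay.
#: The time constants are inert (delta terms are zero) but kept for
#: interface uniformity.
DEFAULT_CN_PARAMS = PathwayParams(
    r_min=250.0, delta_r=0.0, tau_r=1.0, d_min=0.0, delta_d=0.0, tau_d=1.0
)


@dataclass(frozen=True)
class ModelParams:
    """Full model parameterization: per-pathway parameters plus tone scales."""

    sp: PathwayParams
    fp: PathwayParams
    cn: PathwayParams = DEFAULT_CN_PARAMS
    a_r: float = 1.0
    a_d: float = 1.0

    def __post_init__(self) -> None:
        if not self.a_r > 0:
            raise ValueError(f"a_r must be > 0, got {self.a_r}")
        if not self.a_d > 0:
            raise ValueError(f"a_d must be > 0, got {self.a_d}")

    def with_scales(self, a_r: float, a_d: float) -> "ModelParams":
        return replace(self, a_r=a_r, a_d=a_d)

    def to_dict(self) -> dict:
        return {
            "sp": self.sp.to_dict(),
            "fp": self.fp.to_dict(),
            "cn": self.cn.to_dict(),
            "a_r": self.a_r,
            "a_d": self.a_d,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            sp=PathwayParams.from_dict(d["sp"]),
            fp=PathwayParams.from_dict(d["fp"]),
            cn=PathwayParams.from_dict(d.get("cn", DEFAULT_CN_PARAMS.to_dict())),
            a_r=float(d.get("a_r", 1.0)),
            a_d=float(d.get("a_d", 1.0)),
        )


def refractory_period(p: PathwayParams, gap: float, a_r: float = 1.0) -> float:
    """Recovery-dependent refractory period ``a_r*(r_min + delta_r*(1-e^(-g/tau_r)))``.

    ``gap`` may be :data:`FULLY_RECOVERED` (+inf), giving the asymptote
    ``a_r*(r_min + delta_r)``.  Negative gaps are a contract violation:
    only conducted impulses (strictly positive gap) update node state.
    """
    if not a_r > 0:
        raise ValueError(f"a_r must be > 0, got {a_r}")
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    if math.isinf(gap):
        return a_r * (p.r_min + p.delta_r)
    return a_r * (p.r_min + p.delta_r * (1.0 - math.exp(-gap / p.tau_r)))


def conduction_delay(p: PathwayParams, gap: float, a_d: float = 1.0) -> float:
    """Recovery-dependent conduction delay ``a_d*(d_min + delta_d*e^(-g/tau_d))``.

    ``gap`` may be :data:`FULLY_RECOVERED` (+inf), giving the asymptote
    ``a_d*d_min``.
    """
    if not a_d > 0:
        raise ValueError(f"a_d must be > 0, got {a_d}")
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    if math.isinf(gap):
        return a_d * p.d_min
    return a_d * (p.d_min + p.delta_d * math.exp(-gap / p.tau_d))


@dataclass
class NodeState:
    """Mutable per-node history used by the event loop.

    ``last_conducted_arrival`` is ``None`` for a node that has never
    conducted; ``last_gap`` is the excitation gap of the most recent
    conducted impulse (``FULLY_RECOVERED`` initially).
    """

    params: PathwayParams
    last_conducted_arrival: float | None = None
    last_gap: float = FULLY_RECOVERED


def excitation_gap(arrival: float, state: NodeState, a_r: float = 1.0) -> float:
    """Gap between an arrival and the end of the node's previous refractory period.

    Returns :data:`FULLY_RECOVERED` for a node that has never conducted
    (unconditional conduction); may be <= 0 otherwise (blocked).
    """
    if state.last_conducted_arrival is None:
        return FULLY_RECOVERED
    if arrival < state.last_conducted_arrival:
        raise ValueError("events must be processed chronologically")
    return (
        arrival
        - state.last_conducted_arrival
        - refractory_period(state.params, state.last_gap, a_r)
    )


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkTopology:
    """Fixed undirected topology: two chains plus a coupling node.

    Node ids: SP chain ``0..L-1`` (proximal to distal), FP chain
    ``L..2L-1``, CN ``2L``.  Edges: consecutive nodes within each chain,
    the distal-distal cross edge SP_L--FP_L, and SP_L--CN, FP_L--CN.
    """

    chain_length: int
    neighbors: tuple[tuple[int, ...], ...]
    roles: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return 2 * self.chain_length + 1

    @property
    def sp_entry(self) -> int:
        return 0

    @property
    def fp_entry(self) -> int:
        return self.chain_length

    @property
    def cn(self) -> int:
        return 2 * self.chain_length

    def degree(self, node: int) -> int:
        return len(self.neighbors[node])

    def pathway_of(self, node: int) -> int:
        """0 for SP, 1 for FP, 2 for CN."""
        if node < self.chain_length:
            return 0
        if node < 2 * self.chain_length:
            return 1
        return 2


def build_network(chain_length: int = 10) -> NetworkTopology:
    """Build the dual-pathway topology (21 nodes for the default chain length).

    Conduction is bidirectional along every edge, so retrograde wavefronts
    are possible; the adjacency is therefore undirected.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    L = chain_length
    cn = 2 * L
    adj: list[set[int]] = [set() for _ in range(2 * L + 1)]

    def add(u: int, v: int) -> None:
        adj[u].add(v)
        adj[v].add(u)

    for i in range(L - 1):
        add(i, i + 1)              # SP chain
        add(L + i, L + i + 1)      # FP chain
    add(L - 1, 2 * L - 1)          # SP_L -- FP_L
    add(L - 1, cn)                 # SP_L -- CN
    add(2 * L - 1, cn)             # FP_L -- CN

    roles = (
        [f"SP_{i + 1}" for i in range(L)]
        + [f"FP_{i + 1}" for i in range(L)]
        + ["CN"]
    )
    return NetworkTopology(
        chain_length=L,
        neighbors=tuple(tuple(sorted(s)) for s in adj),
        roles=tuple(roles),
    )


@dataclass(frozen=True)
class ScalingSchedule:
    """Piecewise-constant (a_r, a_d) over time: value ``i`` applies on
    ``[start_times[i], start_times[i+1])``; the first value also applies
    before ``start_times[0]``."""

    start_times: np.ndarray  # ms, ascending
    a_r: np.ndarray
    a_d: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.start_times, dtype=np.float64)
        ar = np.asarray(self.a_r, dtype=np.float64)
        ad = np.asarray(self.a_d, dtype=np.float64)
        if not (len(t) == len(ar) == len(ad)) or len(t) == 0:
            raise ValueError("schedule arrays must be non-empty and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("schedule start_times must be strictly increasing")
        if np.any(ar <= 0) or np.any(ad <= 0):
            raise ValueError("schedule scales must be > 0")
        object.__setattr__(self, "start_times", t)
        object.__setattr__(self, "a_r", ar)
        object.__setattr__(self, "a_d", ad)

    @classmethod
    def constant(cls, a_r: float, a_d: float) -> "ScalingSchedule":
        return cls(np.array([0.0]), np.array([a_r]), np.array([a_d]))


def validate_aa_series(aa) -> np.ndarray:
    """Check and coerce an atrial-activation time series (ms)."""
    aa = np.asarray(aa, dtype=np.float64)
    if aa.ndim != 1:
        raise ValueError("AA series must be one-dimensional")
    if aa.size and aa[0] < 0:
        raise ValueError("AA times must be >= 0")
    if aa.size > 1 and np.any(np.diff(aa) <= 0):
        raise ValueError("AA times must be strictly increasing")
    return aa


# ---------------------------------------------------------------------------
# event loop (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _heap_push(ht, hs, hn, size, t, s, n):
    i = size
    ht[i] = t
    hs[i] = s
    hn[i] = n
    while i > 0:
        parent = (i - 1) >> 1
        if ht[i] < ht[parent] or (ht[i] == ht[parent] and hs[i] < hs[parent]):
            ht[i], ht[parent] = ht[parent], ht[i]
            hs[i], hs[parent] = hs[parent], hs[i]
            hn[i], hn[parent] = hn[parent], hn[i]
            i = parent
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(ht, hs, hn, size):
    t = ht[0]
    s = hs[0]
    n = hn[0]
    size -= 1
    ht[0] = ht[size]
    hs[0] = hs[size]
    hn[0] = hn[size]
    i = 0
    while True:
        left = 2 * i + 1
        if left >= size:
            break
        right = left + 1
        child = left
        if right < size and (
            ht[right] < ht[left] or (ht[right] == ht[left] and hs[right] < hs[left])
        ):
            child = right
        if ht[child] < ht[i] or (ht[child] == ht[i] and hs[child] < hs[i]):
            ht[i], ht[child] = ht[child], ht[i]
            hs[i], hs[child] = hs[child], hs[i]
            hn[i], hn[child] = hn[child], hn[i]
            i = child
        else:
            break
    return t, s, n, size


@njit(cache=True)
def _simulate_core(aa, indptr, indices, prow, sp_entry, fp_entry, cn,
                   pmat, sched_t, sched_ar, sched_ad, max_beats):
    n_nodes = prow.shape[0]
    cap = 4 * aa.shape[0] + 256
    ht = np.empty(cap, np.float64)
    hs = np.empty(cap, np.int64)
    hn = np.empty(cap, np.int64)
    size = 0
    seq = 0
    # atrial impulses enter both pathways simultaneously; the SP entry is
    # queued first so that equal-time processing order is deterministic
    for i in range(aa.shape[0]):
        size = _heap_push(ht, hs, hn, size, aa[i], seq, sp_entry)
        seq += 1
        size = _heap_push(ht, hs, hn, size, aa[i], seq, fp_entry)
        seq += 1

    t_prev = np.empty(n_nodes, np.float64)
    r_prev = np.empty(n_nodes, np.float64)
    conducted = np.zeros(n_nodes, np.uint8)

    out_cap = aa.shape[0] + 64
    out = np.empty(out_cap, np.float64)
    nbeats = 0

    si = 0
    nseg = sched_t.shape[0]

    while size > 0:
        t, s, node, size = _heap_pop(ht, hs, hn, size)
        # advance schedule pointer (event times are non-decreasing)
        while si + 1 < nseg and sched_t[si + 1] <= t:
            si += 1
        a_r = sched_ar[si]
        a_d = sched_ad[si]
        row = prow[node]
        if conducted[node] == 0:
            ok = True
            R = a_r * (pmat[row, 0] + pmat[row, 1])
            D = a_d * pmat[row, 3]
        else:
            g = t - t_prev[node] - r_prev[node]
            ok = g > 0.0
            if ok:
                R = a_r * (pmat[row, 0]
                           + pmat[row, 1] * (1.0 - np.exp(-g / pmat[row, 2])))
                D = a_d * (pmat[row, 3] + pmat[row, 4] * np.exp(-g / pmat[row, 5]))
            else:
                R = 0.0
                D = 0.0
        if ok:
            conducted[node] = 1
            t_prev[node] = t
            r_prev[node] = R
            if node == cn:
                if nbeats >= out_cap:
                    new_out = np.empty(2 * out_cap, np.float64)
                    new_out[:out_cap] = out
                    out = new_out
                    out_cap = 2 * out_cap
                out[nbeats] = t + D
                nbeats += 1
                if max_beats > 0 and nbeats >= max_beats:
                    break
            n_nb = indptr[node + 1] - indptr[node]
            if size + n_nb > cap:
                new_cap = 2 * cap + n_nb
                nht = np.empty(new_cap, np.float64)
                nhs = np.empty(new_cap, np.int64)
                nhn = np.empty(new_cap, np.int64)
                nht[:size] = ht[:size]
                nhs[:size] = hs[:size]
                nhn[:size] = hn[:size]
                ht, hs, hn = nht, nhs, nhn
                cap = new_cap
            for j in range(indptr[node], indptr[node + 1]):
                size = _heap_push(ht, hs, hn, size, t + D, seq, indices[j])
                seq += 1
    return out[:nbeats]


def _topology_csr(topo: NetworkTopology) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    indptr = np.zeros(topo.n_nodes + 1, dtype=np.int64)
    indices = []
    for i, nbrs in enumerate(topo.neighbors):
        indptr[i + 1] = indptr[i] + len(nbrs)
        indices.extend(nbrs)
    prow = np.array([topo.pathway_of(i) for i in range(topo.n_nodes)],
                    dtype=np.int64)
    return indptr, np.array(indices, dtype=np.int64), prow


def simulate(
    aa,
    params: ModelParams,
    *,
    chain_length: int = 10,
    max_beats: int | None = None,
    schedule: ScalingSchedule | None = None,
) -> np.ndarray:
    """Propagate an atrial impulse series through the network.

    Parameters
    ----------
    aa : array-like
        Strictly increasing atrial-activation times (ms).
    params : ModelParams
        Pathway parameters and tone scales.  ``params.a_r``/``params.a_d``
        are used when no ``schedule`` is given.
    chain_length : int
        Nodes per pathway (default 10 -> 21-node network).
    max_beats : int, optional
        Stop after this many ventricular activations.
    schedule : ScalingSchedule, optional
        Time-varying (a_r, a_d); overrides the scalar scales in ``params``.

    Returns
    -------
    numpy.ndarray
        Strictly increasing ventricular activation times (ms): the
        transmission times of impulses conducted through the CN.
    """
    aa = validate_aa_series(aa)
    if aa.size == 0:
        return np.empty(0, dtype=np.float64)
    topo = build_network(chain_length)
    indptr, indices, prow = _topology_csr(topo)
    pmat = np.stack(
        [params.sp.as_array(), params.fp.as_array(), params.cn.as_array()]
    )
    if schedule is None:
        schedule = ScalingSchedule.constant(params.a_r, params.a_d)
    return _simulate_core(
        aa, indptr, indices, prow,
        topo.sp_entry, topo.fp_entry, topo.cn,
        pmat,
        schedule.start_times, schedule.a_r, schedule.a_d,
        0 if max_beats is None else int(max_beats),
    )
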