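"""Time-stratified historical biogeography: DEC-family models and stochastic maps.

Ranges are nonempty subsets (up to ``max_range_size``) of up to eight
zoogeographic realms (PA, OR, IN, SA, AT, AU, NA, NT).  Anagenetic evolution
is a continuous-time Markov chain: a realm b is gained from range R at rate
d * sum_{a in R} m(a, b), where m is the epoch's pairwise dispersal
multiplier (adjacent plates 0.75, one barrier 0.5, two or more barriers
1e-6), and ranges larger than one realm lose a resident realm at rate e.
Epoch boundaries splice branch transition matrices, so the dispersal graph
follows plate tectonics through time.

Cladogenesis differs by scheme: DEC allows single-area sympatry, subset
sympatry and single-area vicariance; DIVALIKE allows single-area sympatry and
unrestricted vicariance (no subset sympatry); BAYAREALIKE copies the range to
both daughters.  The +j variants add founder-event speciation into a realm
outside the parent range with weight j.  Models are ML-fit and compared by
AICc; biogeographic stochastic mapping (BSM) samples explicit event histories
conditional on the tips and counts dispersal events per My and per realm pair.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .trees import TimeTree

__all__ = [
    "REALMS", "Epoch", "RealmHistory", "BiogeoModel",
    "make_states", "range_to_string", "range_from_string",
    "build_q", "loglik", "fit", "bsm", "simulate_ranges",
]

REALMS = ["PA", "OR", "IN", "SA", "AT", "AU", "NA", "NT"]

BARRIER_MULTIPLIERS = {"adjacent": 0.75, "one_barrier": 0.5, "isolated": 1e-6}


@dataclass(eq=False)
class Epoch:
    start: float  # older bound, Ma
    end: float    # younger bound, Ma
    multipliers: np.ndarray  # (n_realms, n_realms) symmetric

    def __post_init__(self):
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if self.start <= self.end:
            raise ValueError("epoch start (older) must exceed end (younger)")
        if not np.allclose(self.multipliers, self.multipliers.T):
            raise ValueError("multiplier matrix must be symmetric")


@dataclass
class RealmHistory:
    realms: list[str]
    epochs: list[Epoch]  # ordered old -> young, tiling the tree span

    def __post_init__(self):
        if len(self.realms) > 8:
            raise ValueError("at most 8 realms")
        es = sorted(self.epochs, key=lambda e: -e.start)
        for a, b in zip(es, es[1:]):
            if not np.isclose(a.end, b.start):
                raise ValueError("epochs must tile the span without gaps/overlap")
        self.epochs = es

    @property
    def n_realms(self) -> int:
        return len(self.realms)

    @property
    def span(self) -> tuple[float, float]:
        return self.epochs[0].start, self.epochs[-1].end

    def epoch_at(self, age: float) -> Epoch:
        for e in self.epochs:
            if e.start >= age > e.end or (age <= self.epochs[-1].end + 1e-12
                                          and e is self.epochs[-1]):
                return e
        if age > self.epochs[0].start:
            return self.epochs[0]
        return self.epochs[-1]

    def boundaries_between(self, older: float, younger: float) -> list[float]:
        cuts = [e.end for e in self.epochs if younger < e.end < older]
        return sorted(cuts, reverse=True)

    @staticmethod
    def uniform(realms, start: float, multiplier: float = 0.75) -> "RealmHistory":
        n = len(realms)
        m = np.full((n, n), multiplier)
        np.fill_diagonal(m, 1.0)
        return RealmHistory(list(realms), [Epoch(start, 0.0, m)])


@dataclass
class BiogeoModel:
    d: float = 0.01   # per-My dispersal (range-gain) rate
    e: float = 0.005  # per-My extirpation (range-loss) rate
    j: float = 0.0    # founder-event weight, 0 disables
    scheme: str = "DEC"
    max_range_size: int = 2

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("d and e must be nonnegative")
        if not 0 <= self.j < 3:
            raise ValueError("j must lie in [0, 3)")
        if self.scheme not in ("DEC", "DIVALIKE", "BAYAREALIKE"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


# ----------------------------------------------------------- range state space

def make_states(n_realms: int, max_range_size: int) -> list[int]:
    """Bitmask range states: all nonempty realm subsets up to max size."""
    states = [s for s in range(1, 1 << n_realms)
              if bin(s).count("1") <= max_range_size]
    states.sort(key=lambda s: (bin(s).count("1"), s))
    return states


def _bits(s: int) -> list[int]:
    return [i for i in range(8) if s >> i & 1]


def range_to_string(state: int, realms=REALMS) -> str:
    return "+".join(realms[i] for i in _bits(state))


def range_from_string(text: str, realms=REALMS) -> int:
    s = 0
    for part in text.split("+"):
        s |= 1 << realms.index(part.strip())
    return s


# --------------------------------------------------------- anagenetic generator

def build_q(model: BiogeoModel, multipliers: np.ndarray,
            states: list[int]) -> np.ndarray:
    """Instantaneous generator over range states for one epoch.

    Off-diagonal entries: realm gain at d * sum_{a in R} m(a, b) and realm
    loss at e per resident realm (only for ranges of size >= 2, since the
    empty range is excluded from the state space).  Rows sum to zero.
    """
    idx = {s: k for k, s in enumerate(states)}
    S = len(states)
    Q = np.zeros((S, S))
    n = multipliers.shape[0]
    for k, s in enumerate(states):
        bits = _bits(s)
        if len(bits) < model.max_range_size:
            for b in range(n):
                if s >> b & 1:
                    continue
                rate = model.d * sum(multipliers[a, b] for a in bits)
                Q[k, idx[s | (1 << b)]] += rate
        if len(bits) >= 2:
            for a in bits:
                Q[k, idx[s & ~(1 << a)]] += model.e
    Q[np.diag_indices(S)] = -Q.sum(axis=1)
    return Q


# ----------------------------------------------------------- cladogenesis table

def cladogenesis_events(parent: int, model: BiogeoModel, n_realms: int,
                        states_set: set[int]) -> list[tuple[int, int, float]]:
    """Allowed (left, right, probability) daughter-range pairs at a node."""
    bits = _bits(parent)
    events: list[tuple[int, int, float]] = []
    w_j = model.j

    def add(l, r, w):
        events.append((l, r, w))

    if model.scheme == "BAYAREALIKE":
        add(parent, parent, 1.0)
    elif len(bits) == 1:
        add(parent, parent, 1.0)
    else:
        singles = [1 << a for a in bits]
        if model.scheme == "DEC":
            for s in singles:  # subset sympatry + single-area vicariance
                add(s, parent, 1.0)
                add(parent, s, 1.0)
                comp = parent & ~s
                add(s, comp, 1.0)
                add(comp, s, 1.0)
        else:  # DIVALIKE: vicariance into any two disjoint covering subsets
            for sub in range(1, parent):
                if sub & ~parent:
                    continue
                comp = parent & ~sub
                if comp == 0:
                    continue
                if sub in states_set and comp in states_set:
                    add(sub, comp, 1.0)
    if w_j > 0:
        for b in range(n_realms):
            if parent >> b & 1:
                continue
            add(parent, 1 << b, w_j)
            add(1 << b, parent, w_j)
    tot = sum(w for *_, w in events)
    return [(l, r, w / tot) for l, r, w in events]


# ------------------------------------------------------------------ likelihood

class _Machinery:
    """Cached state space, per-epoch generators, and per-branch segment matrices."""

    def __init__(self, tree: TimeTree, model: BiogeoModel, history: RealmHistory):
        self.tree = tree
        self.model = model
        self.history = history
        self.states = make_states(history.n_realms, model.max_range_size)
        self.idx = {s: k for k, s in enumerate(self.states)}
        self.S = len(self.states)
        self._Q: dict[int, np.ndarray] = {}
        self._segments: dict[int, list] = {}
        self._clado: dict[int, list] = {}
        for k, e in enumerate(history.epochs):
            self._Q[k] = build_q(model, e.multipliers, self.states)

    def q_at(self, age: float) -> np.ndarray:
        e = self.history.epoch_at(age)
        return self._Q[self.history.epochs.index(e)]

    def branch_segments(self, node: int):
        """List of (age_older, age_younger, Q) pieces for the branch above node."""
        if node in self._segments:
            return self._segments[node]
        t = self.tree
        a_old = float(t.age[t.parent[node]])
        a_new = float(t.age[node])
        cuts = [a_old] + self.history.boundaries_between(a_old, a_new) + [a_new]
        segs = []
        for hi, lo in zip(cuts, cuts[1:]):
            if hi - lo <= 0:
                continue
            mid = 0.5 * (hi + lo)
            segs.append((hi, lo, self.q_at(mid)))
        self._segments[node] = segs
        return segs

    def branch_matrix(self, node: int) -> np.ndarray:
        M = np.eye(self.S)
        for hi, lo, Q in self.branch_segments(node):
            M = M @ expm(Q * (hi - lo))
        return M

    def clado(self, parent_state: int):
        if parent_state not in self._clado:
            self._clado[parent_state] = cladogenesis_events(
                parent_state, self.model, self.history.n_realms, set(self.states))
        return self._clado[parent_state]


def _tip_state_vector(mach: _Machinery, tip_ranges, label: str) -> np.ndarray:
    r = tip_ranges[label]
    if isinstance(r, str):
        r = range_from_string(r, mach.history.realms)
    if r not in mach.idx:
        raise ValueError(f"tip range of {label!r} exceeds max_range_size or is empty")
    v = np.zeros(mach.S)
    v[mach.idx[r]] = 1.0
    return v


def _conditional_likelihoods(mach: _Machinery, tip_ranges):
    tree = mach.tree
    CL = np.zeros((tree.n_nodes, mach.S))
    DL = np.zeros((tree.n_nodes, mach.S))  # after-branch (at parent end)
    for i in tree.postorder:
        if tree.is_tip(i):
            CL[i] = _tip_state_vector(mach, tip_ranges, tree.labels[i])
        else:
            kids = tree.children[i]
            if len(kids) != 2:
                raise ValueError("biogeography requires a binary tree")
            for k, s in enumerate(mach.states):
                tot = 0.0
                for l, r, w in mach.clado(s):
                    tot += w * DL[kids[0]][mach.idx[l]] * DL[kids[1]][mach.idx[r]]
                CL[i, k] = tot
        if i != tree.root:
            DL[i] = mach.branch_matrix(i) @ CL[i]
    return CL, DL


def loglik(tree: TimeTree, tip_ranges, model: BiogeoModel,
           history: RealmHistory) -> float:
    """Pruning log-likelihood with a flat root prior over range states."""
    mach = _Machinery(tree, model, history)
    CL, _ = _conditional_likelihoods(mach, tip_ranges)
    L = CL[tree.root].mean()  # flat prior 1/S
    if L <= 0:
        return -np.inf
    return float(np.log(L))


# --------------------------------------------------------------------- fitting

_SCHEME_K = {"DEC": 2, "DIVALIKE": 2, "BAYAREALIKE": 2}


def fit(tree: TimeTree, tip_ranges, history: RealmHistory,
        schemes=("DEC", "DIVALIKE", "BAYAREALIKE"), with_j: bool = True,
        max_range_size: int = 2) -> pd.DataFrame:
    """ML fit of the requested schemes (and optionally their +j variants).

    Returns an AICc table sorted by AICc with boundary-convergence flags.
    """
    from scipy import optimize

    n = tree.n_tips
    variants = []
    for s in schemes:
        variants.append((s, False))
        if with_j:
            variants.append((s, True))
    rows = []
    for scheme, use_j in variants:
        lo = np.array([np.log(1e-6)] * 2 + ([0.0] if use_j else []))
        hi = np.array([np.log(5.0)] * 2 + ([2.99] if use_j else []))

        def nll(theta):
            # Nelder-Mead is unbounded; reject out-of-box proposals so the
            # matrix exponential never sees astronomically large rates
            if np.any(theta < lo) or np.any(theta > hi):
                return 1e10
            d, e = np.exp(theta[0]), np.exp(theta[1])
            j = theta[2] if use_j else 0.0
            try:
                m = BiogeoModel(d=d, e=e, j=j, scheme=scheme,
                                max_range_size=max_range_size)
                return -loglik(tree, tip_ranges, m, history)
            except Exception:
                return 1e10

        x0 = [np.log(0.02), np.log(0.01)] + ([0.1] if use_j else [])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": 400})
        theta = np.clip(res.x, lo, hi)
        bounds = list(zip(lo, hi))
        ll = -nll(theta)
        d, e = float(np.exp(theta[0])), float(np.exp(theta[1]))
        j = float(theta[2]) if use_j else 0.0
        k = _SCHEME_K[scheme] + (1 if use_j else 0)
        aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / max(n - k - 1, 1)
        boundary = bool(np.any(np.isclose(theta, [b[0] for b in bounds])) or
                        np.any(np.isclose(theta, [b[1] for b in bounds])))
        rows.append(dict(scheme=scheme + ("+j" if use_j else ""), d=d, e=e, j=j,
                         logL=ll, k=k, AICc=aicc, boundary=boundary))
    tab = pd.DataFrame(rows).set_index("scheme").sort_values("AICc")
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    return tab


# --------------------------------------------------- endpoint-conditioned paths

def _sample_segment_path(Q: np.ndarray, a: int, b: int, t: float,
                         rng: np.random.Generator, max_reject: int = 1000):
    """Jump chain (times from segment start, states) of a CTMC bridge a -> b.

    Rejection sampling first (forced first jump when a != b), then an exact
    uniformization bridge after ``max_reject`` failures.
    """
    S = Q.shape[0]
    rates = -np.diag(Q)

    def forward(start, duration, force_first):
        path = []
        s, tau = start, 0.0
        first = True
        while True:
            r = rates[s]
            if r <= 0:
                break
            if first and force_first:
                u = rng.uniform(0, 1 - np.exp(-r * (duration - tau)))
                dt = -np.log(1 - u) / r
            else:
                dt = rng.exponential(1.0 / r)
            if tau + dt >= duration:
                break
            tau += dt
            p = Q[s].copy()
            p[s] = 0.0
            p = np.clip(p, 0, None)
            p /= p.sum()
            s = rng.choice(S, p=p)
            path.append((tau, s))
            first = False
        return path, s

    force = a != b
    for _ in range(max_reject):
        path, end = forward(a, t, force)
        if end == b and (path or a == b):
            return path
        if end == b and not force:
            return path
    return _uniformization_bridge(Q, a, b, t, rng)


def _uniformization_bridge(Q: np.ndarray, a: int, b: int, t: float,
                           rng: np.random.Generator):
    S = Q.shape[0]
    lam = max(float(np.max(-np.diag(Q))), 1e-12)
    R = np.eye(S) + Q / lam
    powers = [np.eye(S)]
    # P(N = n | a, b, t) proportional to Poisson(lam t; n) * R^n[a, b]
    pab = expm(Q * t)[a, b]
    if pab <= 0:
        raise RuntimeError("impossible endpoint pair in uniformization bridge")
    logpois = -lam * t
    weights = []
    n = 0
    total = 0.0
    target = rng.uniform()
    while True:
        if n >= len(powers):
            powers.append(powers[-1] @ R)
        w = np.exp(logpois) * powers[n][a, b] / pab
        weights.append(w)
        total += w
        if total >= target or n > 10_000:
            break
        n += 1
        logpois += np.log(lam * t) - np.log(n)
    nsteps = n
    times = np.sort(rng.uniform(0, t, nsteps))
    path = []
    cur = a
    for k in range(nsteps):
        rem = nsteps - k - 1
        while rem >= len(powers):
            powers.append(powers[-1] @ R)
        probs = R[cur] * powers[rem][:, b]
        ssum = probs.sum()
        if ssum <= 0:
            probs = R[cur].copy()
            ssum = probs.sum()
        probs = probs / ssum
        nxt = rng.choice(S, p=probs)
        if nxt != cur:
            path.append((float(times[k]), int(nxt)))
        cur = nxt
    return path


# ----------------------------------------------------------------------- BSM

@dataclass
class StochasticMap:
    """One sampled biogeographic history: explicit events along branches."""
    events: pd.DataFrame          # columns: age_ma, type, node, from_range, to_range, realm_from, realm_to
    node_states: dict[int, int]   # range state at each node (post-cladogenesis start of branch omitted)

    def dispersal_count(self) -> int:
        return int((self.events["type"].isin(["dispersal", "founder"])).sum())


def _attribute_pair(from_state: int, gained: int, mult: np.ndarray,
                    realms) -> tuple[str, str]:
    """Source realm for a gain event: resident realm with maximal multiplier."""
    bits = _bits(from_state)
    src = max(bits, key=lambda a: (mult[a, gained], -a))
    return realms[src], realms[gained]


def bsm(tree: TimeTree, tip_ranges, model: BiogeoModel, history: RealmHistory,
        n_maps: int = 200, seed: int | None = None,
        bin_width: float = 1.0) -> dict:
    """Biogeographic stochastic mapping conditional on the tip ranges.

    Samples ``n_maps`` joint histories (node ranges from conditional
    likelihoods, branch histories from endpoint-conditioned CTMC bridges),
    then summarizes dispersal events per ``bin_width``-My bin and the
    percentage of dispersal events per realm pair (summing to 100).
    """
    rng = np.random.default_rng(seed)
    mach = _Machinery(tree, model, history)
    CL, DL = _conditional_likelihoods(mach, tip_ranges)
    if not np.isfinite(np.log(max(CL[tree.root].mean(), 0))):
        raise ValueError("model has zero likelihood for these tips")
    seg_mats: dict[int, list] = {}
    for i in range(tree.n_nodes):
        if i == tree.root:
            continue
        segs = mach.branch_segments(i)
        seg_mats[i] = [(hi, lo, Q, expm(Q * (hi - lo))) for hi, lo, Q in segs]

    maps: list[StochasticMap] = []
    root_age = float(tree.age[tree.root])
    edges = np.arange(0.0, np.ceil(root_age) + bin_width, bin_width)
    per_my = np.zeros((n_maps, len(edges) - 1))
    pair_counts: dict[tuple[str, str], float] = {}

    for m_i in range(n_maps):
        ev_rows = []
        node_state: dict[int, int] = {}
        pr = CL[tree.root] / CL[tree.root].sum()
        node_state[tree.root] = mach.states[rng.choice(mach.S, p=pr)]
        start_state: dict[int, int] = {}  # state at the TOP (parent end) of branch
        stack = [tree.root]
        while stack:
            nd = stack.pop()
            s = node_state[nd]
            if tree.is_tip(nd):
                continue
            kids = tree.children[nd]
            events = mach.clado(s)
            wts = np.array([w * DL[kids[0]][mach.idx[l]] * DL[kids[1]][mach.idx[r]]
                            for l, r, w in events])
            tot = wts.sum()
            if tot <= 0:
                raise RuntimeError("no viable cladogenetic event")
            l, r, _ = events[rng.choice(len(events), p=wts / tot)]
            for child_state, child in ((l, kids[0]), (r, kids[1])):
                # founder / cladogenetic dispersal: daughter outside parent range
                if child_state & ~s:
                    gained = _bits(child_state & ~s)[0]
                    mult = mach.history.epoch_at(float(tree.age[nd])).multipliers
                    fr, to = _attribute_pair(s, gained, mult, history.realms)
                    ev_rows.append(dict(age_ma=float(tree.age[nd]),
                                        type="founder", node=int(child),
                                        from_range=range_to_string(s, history.realms),
                                        to_range=range_to_string(child_state, history.realms),
                                        realm_from=fr, realm_to=to))
                start_state[child] = child_state
                # branch path: sample child-end state, then bridge per segment
                cur = start_state[child]
                segs = seg_mats[child]
                # sample states at each internal boundary then the child end
                states_seq = [mach.idx[cur]]
                Mrest = [np.eye(mach.S)]
                for hi, lo, Q, M in reversed(segs):
                    Mrest.append(M @ Mrest[-1])
                Mrest = Mrest[::-1]  # Mrest[k] = product of segment mats k..end
                target = CL[child]
                for k, (hi, lo, Q, M) in enumerate(segs):
                    after = Mrest[k + 1]
                    probs = M[states_seq[-1]] * (after @ target)
                    probs = np.clip(probs, 0, None)
                    probs /= probs.sum()
                    states_seq.append(int(rng.choice(mach.S, p=probs)))
                # bridge each segment
                for k, (hi, lo, Q, M) in enumerate(segs):
                    a, b = states_seq[k], states_seq[k + 1]
                    path = _sample_segment_path(Q, a, b, hi - lo, rng)
                    cur_s = mach.states[a]
                    for tau, s_idx in path:
                        new_s = mach.states[s_idx]
                        age = hi - tau
                        if bin(new_s).count("1") > bin(cur_s).count("1"):
                            gained = _bits(new_s & ~cur_s)[0]
                            mult = mach.history.epoch_at(age).multipliers
                            fr, to = _attribute_pair(cur_s, gained, mult,
                                                     history.realms)
                            ev_rows.append(dict(
                                age_ma=age, type="dispersal", node=int(child),
                                from_range=range_to_string(cur_s, history.realms),
                                to_range=range_to_string(new_s, history.realms),
                                realm_from=fr, realm_to=to))
                        else:
                            ev_rows.append(dict(
                                age_ma=age, type="extirpation", node=int(child),
                                from_range=range_to_string(cur_s, history.realms),
                                to_range=range_to_string(new_s, history.realms),
                                realm_from="", realm_to=""))
                        cur_s = new_s
                node_state[child] = mach.states[states_seq[-1]]
                stack.append(child)
        ev = pd.DataFrame(ev_rows, columns=["age_ma", "type", "node",
                                            "from_range", "to_range",
                                            "realm_from", "realm_to"])
        maps.append(StochasticMap(events=ev, node_states=node_state))
        disp = ev[ev["type"].isin(["dispersal", "founder"])]
        if len(disp):
            hist, _ = np.histogram(disp["age_ma"].to_numpy(), bins=edges)
            per_my[m_i] = hist
            for _, row in disp.iterrows():
                key = (row["realm_from"], row["realm_to"])
                pair_counts[key] = pair_counts.get(key, 0.0) + 1.0

    total_pairs = sum(pair_counts.values())
    pair_pct = {f"{a}->{b}": 100.0 * c / total_pairs
                for (a, b), c in sorted(pair_counts.items())} if total_pairs else {}
    series = pd.DataFrame({
        "bin_younger": edges[:-1], "bin_older": edges[1:],
        "mean_dispersal_events": per_my.mean(axis=0),
        "sd_dispersal_events": per_my.std(axis=0),
    })
    return {"maps": maps, "per_my": series, "realm_pair_percent": pair_pct,
            "mean_total_dispersals": float(per_my.sum(axis=1).mean())}


# ----------------------------------------------------------- forward simulation

def simulate_ranges(tree: TimeTree, model: BiogeoModel, history: RealmHistory,
                    seed: int | None = None, root_state: int | None = None,
                    rate_modifier=None) -> dict:
    """Simulate range evolution forward along the tree (ground truth for tests).

    ``rate_modifier(age) -> float`` optionally scales the dispersal rate d
    through time (thinning is used, bounded by the modifier's maximum over
    each branch evaluated on a fine grid).  Returns tip ranges, node ranges,
    and the full event list.
    """
    rng = np.random.default_rng(seed)
    states = make_states(history.n_realms, model.max_range_size)
    idx = {s: k for k, s in enumerate(states)}
    if root_state is None:
        root_state = 1 << rng.integers(history.n_realms)
    node_state = {tree.root: root_state}
    events = []

    def q_for(age, mod):
        m = BiogeoModel(d=model.d * mod, e=model.e, j=model.j,
                        scheme=model.scheme, max_range_size=model.max_range_size)
        return build_q(m, history.epoch_at(age).multipliers, states)

    order = tree.preorder
    for nd in order:
        if tree.is_tip(nd):
            continue
        s = node_state[nd]
        ev = cladogenesis_events(s, model, history.n_realms, set(states))
        probs = np.array([w for *_, w in ev])
        l, r, _ = ev[rng.choice(len(ev), p=probs / probs.sum())]
        for child_state, child in zip((l, r), tree.children[nd]):
            a_old = float(tree.age[nd])
            a_new = float(tree.age[child])
            cur = child_state
            age = a_old
            # thinning over the branch
            while age > a_new + 1e-12:
                grid = np.linspace(age, a_new, 8)
                mmax = max((rate_modifier(g) for g in grid), default=1.0) \
                    if rate_modifier else 1.0
                Qb = q_for(age, mmax)
                rate = -Qb[idx[cur], idx[cur]]
                if rate <= 0:
                    break
                dt = rng.exponential(1.0 / rate)
                nxt_age = age - dt
                cut = history.boundaries_between(age, a_new)
                limit = max(cut[0] if cut else a_new, a_new)
                if nxt_age <= limit:
                    age = limit
                    if np.isclose(age, a_new):
                        break
                    continue
                age = nxt_age
                mod_here = rate_modifier(age) if rate_modifier else 1.0
                Qh = q_for(age, mod_here)
                # accept with ratio of actual total rate to bounding rate
                if rng.uniform() > -Qh[idx[cur], idx[cur]] / rate:
                    continue
                p = Qh[idx[cur]].copy()
                p[idx[cur]] = 0
                p = np.clip(p, 0, None)
                nxt = states[rng.choice(len(states), p=p / p.sum())]
                kind = "dispersal" if bin(nxt).count("1") > bin(cur).count("1") \
                    else "extirpation"
                events.append(dict(age_ma=age, type=kind, node=int(child),
                                   from_range=range_to_string(cur, history.realms),
                                   to_range=range_to_string(nxt, history.realms)))
                cur = nxt
            node_state[child] = cur
    tip_ranges = {tree.labels[t]: node_state[int(t)] for t in tree.tips}
    return {"tip_ranges": tip_ranges, "node_states": node_state,
            "events": pd.DataFrame(events, columns=["age_ma", "type", "node",
                                                    "from_range", "to_range"])}
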