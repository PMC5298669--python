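"""Identity tracking: Kalman prediction, Hungarian assignment, heading
confirmation, and greedy closest-neighbor repair.

Each fly carries a constant-velocity Kalman state ``x = (x, y, vx, vy)``
with transition

    A = [[1, 0, dt, 0],
         [0, 1, 0, dt],
         [0, 0, 1,  0],
         [0, 0, 0,  1]],        x_{k+1} = A x_k.

Per frame, predicted tracker positions (workers) are matched to detections
(jobs) by Euclidean distance with the Hungarian algorithm on a
dummy-padded cost matrix.  Accepted pairs must also agree in heading
direction within a tolerance — a fly that stops and walks backward keeps
its heading even though its velocity reverses, which is exactly the case
where distance-only matching swaps identities.  Rejected pairs (including
any pair touching a dummy) are re-matched greedily, closest first, using
the trackers' *pre-prediction* positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "TrackerState",
    "CostMatrix",
    "Assignment",
    "TrackConfig",
    "kf_predict",
    "kf_update",
    "build_cost_matrix",
    "hungarian_assign",
    "closest_neighbor_assign",
    "heading_check",
    "track_step",
]


@dataclass
class TrackerState:
    id: int
    state: np.ndarray  # (4,) = x, y, vx, vy
    covariance: np.ndarray  # (4, 4)
    heading: np.ndarray | None = None  # unit vector or None
    age: int = 0
    missed: int = 0
    matched: bool = True

    @property
    def position(self) -> np.ndarray:
        return self.state[:2].copy()

    @property
    def velocity(self) -> np.ndarray:
        return self.state[2:].copy()


@dataclass(frozen=True)
class CostMatrix:
    """Rectangular (dummy-padded) distance matrix, workers x jobs."""

    costs: np.ndarray
    is_dummy_row: np.ndarray  # bool per row
    is_dummy_col: np.ndarray  # bool per column
    dummy_cost: float


@dataclass
class Assignment:
    pairs: list[tuple[int, int]]  # (worker, job) — real indices only
    unmatched_workers: list[int]
    unmatched_jobs: list[int]
    total_cost: float


@dataclass(frozen=True)
class TrackConfig:
    """Tracking parameters.

    ``dt`` is the inter-frame interval (frames of 1 internally; seconds at
    the I/O layer).  ``gate`` is the largest plausible per-frame travel;
    the dummy cost is ``dummy_cost_factor * gate`` so that a detection
    farther than the gate from every prediction prefers a dummy (birth /
    coast) over a bad match.  Q comes from a white-acceleration model with
    ``q_accel_sd``; R is isotropic with ``r_sd``.  Neither noise covariance
    is a measured quantity — both are tuning defaults.
    """

    dt: float = 1.0
    gate: float = 50.0
    dummy_cost_factor: float = 1.5
    heading_tolerance: float = np.pi / 2
    max_missed: int = 10
    q_accel_sd: float = 10.0
    r_sd: float = 2.0
    use_heading_check: bool = True

    @property
    def dummy_cost(self) -> float:
        return self.dummy_cost_factor * self.gate


def _transition(dt: float) -> np.ndarray:
    return np.array(
        [
            [1.0, 0.0, dt, 0.0],
            [0.0, 1.0, 0.0, dt],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def _process_noise(dt: float, accel_sd: float) -> np.ndarray:
    # white-acceleration (piecewise constant) model
    q = accel_sd**2
    d2, d3, d4 = dt**2, dt**3, dt**4
    return q * np.array(
        [
            [d4 / 4, 0.0, d3 / 2, 0.0],
            [0.0, d4 / 4, 0.0, d3 / 2],
            [d3 / 2, 0.0, d2, 0.0],
            [0.0, d3 / 2, 0.0, d2],
        ]
    )


_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])


def new_tracker(
    tid: int,
    position: tuple[float, float] | np.ndarray,
    heading: np.ndarray | None = None,
    pos_var: float = 4.0,
    vel_var: float = 100.0,
) -> TrackerState:
    """Fresh tracker at a detection; velocity starts at zero."""
    state = np.array([position[0], position[1], 0.0, 0.0])
    cov = np.diag([pos_var, pos_var, vel_var, vel_var])
    return TrackerState(id=tid, state=state, covariance=cov, heading=heading)


def kf_predict(t: TrackerState, dt: float = 1.0, q_accel_sd: float = 10.0) -> TrackerState:
    """Constant-velocity prediction: x <- A x, P <- A P A' + Q."""
    a = _transition(dt)
    state = a @ t.state
    cov = a @ t.covariance @ a.T + _process_noise(dt, q_accel_sd)
    return replace(t, state=state, covariance=cov)


def kf_update(
    t: TrackerState, z: tuple[float, float] | np.ndarray, r_sd: float = 2.0
) -> TrackerState:
    """Standard Kalman correction against a position measurement."""
    z = np.asarray(z, dtype=float)
    r = r_sd**2 * np.eye(2)
    p = t.covariance
    s = _H @ p @ _H.T + r
    k = p @ _H.T @ np.linalg.solve(s, np.eye(2))
    innov = z - _H @ t.state
    state = t.state + k @ innov
    ikh = np.eye(4) - k @ _H
    cov = ikh @ p @ ikh.T + k @ r @ k.T  # Joseph form keeps P symmetric PSD
    return replace(t, state=state, covariance=cov)


def build_cost_matrix(
    workers: np.ndarray, jobs: np.ndarray, dummy_cost: float
) -> CostMatrix:
    """Euclidean distances padded with dummy rows and columns.

    Padding to ``(n + m) x (m + n)`` lets every worker and every job go
    unmatched at ``dummy_cost``; dummy-dummy entries cost zero.
    """
    workers = np.atleast_2d(np.asarray(workers, dtype=float))
    jobs = np.atleast_2d(np.asarray(jobs, dtype=float))
    n = 0 if workers.size == 0 else workers.shape[0]
    m = 0 if jobs.size == 0 else jobs.shape[0]
    costs = np.zeros((n + m, m + n))
    if n and m:
        d = workers[:, None, :] - jobs[None, :, :]
        costs[:n, :m] = np.hypot(d[..., 0], d[..., 1])
    costs[:n, m:] = dummy_cost  # worker -> dummy job
    costs[n:, :m] = dummy_cost  # dummy worker -> job
    is_dummy_row = np.arange(n + m) >= n
    is_dummy_col = np.arange(m + n) >= m
    return CostMatrix(
        costs=costs,
        is_dummy_row=is_dummy_row,
        is_dummy_col=is_dummy_col,
        dummy_cost=float(dummy_cost),
    )


def _as_cost_matrix(c: CostMatrix | np.ndarray) -> CostMatrix:
    if isinstance(c, CostMatrix):
        return c
    arr = np.asarray(c, dtype=float)
    return CostMatrix(
        costs=arr,
        is_dummy_row=np.zeros(arr.shape[0], dtype=bool),
        is_dummy_col=np.zeros(arr.shape[1], dtype=bool),
        dummy_cost=np.inf,
    )


def _finish(
    c: CostMatrix, raw_pairs: list[tuple[int, int]]
) -> Assignment:
    n_real_w = int((~c.is_dummy_row).sum())
    n_real_j = int((~c.is_dummy_col).sum())
    pairs = [
        (w, j)
        for w, j in raw_pairs
        if not c.is_dummy_row[w] and not c.is_dummy_col[j]
    ]
    matched_w = {w for w, _ in pairs}
    matched_j = {j for _, j in pairs}
    total = float(sum(c.costs[w, j] for w, j in pairs))
    return Assignment(
        pairs=sorted(pairs),
        unmatched_workers=[w for w in range(n_real_w) if w not in matched_w],
        unmatched_jobs=[j for j in range(n_real_j) if j not in matched_j],
        total_cost=total,
    )


def hungarian_assign(c: CostMatrix | np.ndarray) -> Assignment:
    """Globally optimal assignment (minimum total cost).

    Pairs involving a dummy row or column are reported as unmatched.
    """
    c = _as_cost_matrix(c)
    rows, cols = linear_sum_assignment(c.costs)
    return _finish(c, list(zip(rows.tolist(), cols.tolist())))


def closest_neighbor_assign(c: CostMatrix | np.ndarray) -> Assignment:
    """Greedy assignment: repeatedly fix the globally smallest entry.

    Take the minimum cost in the matrix, commit that (worker, job) pair,
    delete its row and column, and repeat until a side is exhausted.  Ties
    break on lowest row index, then lowest column index.  Locally optimal
    only — on adversarial matrices the total exceeds the Hungarian total.
    """
    c = _as_cost_matrix(c)
    costs = c.costs.copy()
    nr, nc = costs.shape
    row_alive = np.ones(nr, dtype=bool)
    col_alive = np.ones(nc, dtype=bool)
    raw_pairs: list[tuple[int, int]] = []
    for _ in range(min(nr, nc)):
        sub = costs[np.ix_(row_alive, col_alive)]
        if sub.size == 0:
            break
        flat = int(np.argmin(sub))  # argmin is row-major: lowest row then col
        ri, ci = divmod(flat, sub.shape[1])
        rows_idx = np.flatnonzero(row_alive)
        cols_idx = np.flatnonzero(col_alive)
        w, j = int(rows_idx[ri]), int(cols_idx[ci])
        raw_pairs.append((w, j))
        row_alive[w] = False
        col_alive[j] = False
    return _finish(c, raw_pairs)


def heading_angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute angle between two unit vectors, in [0, pi]."""
    dot = float(np.clip(np.dot(u, v), -1.0, 1.0))
    if dot >= 1.0 - 1e-12:
        return 0.0  # identical directions: avoid arccos rounding noise
    return float(np.arccos(dot))


def heading_check(
    assignment: Assignment,
    tracker_headings: list[np.ndarray | None],
    detection_headings: list[np.ndarray | None],
    tolerance: float,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split matched pairs into heading-consistent and rejected.

    A pair is accepted when the angle between the tracker's stored heading
    and the detection's heading is within ``tolerance``.  A missing heading
    on either side accepts the pair (heading is confirmatory evidence, not
    a requirement).  Dummy pairs never appear here: ``hungarian_assign``
    already reports them as unmatched.
    """
    accepted: list[tuple[int, int]] = []
    rejected: list[tuple[int, int]] = []
    for w, j in assignment.pairs:
        th = tracker_headings[w]
        dh = detection_headings[j]
        if th is None or dh is None:
            accepted.append((w, j))
        elif heading_angle_between(np.asarray(th), np.asarray(dh)) <= tolerance:
            accepted.append((w, j))
        else:
            rejected.append((w, j))
    return accepted, rejected


def track_step(
    trackers: list[TrackerState],
    detections: list[tuple[np.ndarray, np.ndarray | None]],
    cfg: TrackConfig,
    next_id: int | None = None,
) -> list[TrackerState]:
    """Advance all trackers by one frame against one frame's detections.

    Pipeline: predict -> Hungarian on predicted positions -> heading gate
    -> greedy closest-neighbor repair of rejected pairs using
    *pre-prediction* positions -> Kalman update matched trackers, coast
    unmatched ones, spawn trackers on unmatched detections (zero initial
    velocity), retire trackers missing longer than ``max_missed``.
    """
    if next_id is None:
        next_id = max((t.id for t in trackers), default=0) + 1
    pre_positions = [t.position for t in trackers]
    predicted = [kf_predict(t, cfg.dt, cfg.q_accel_sd) for t in trackers]
    det_pos = [np.asarray(p, dtype=float) for p, _ in detections]
    det_head = [h for _, h in detections]

    if predicted and det_pos:
        cm = build_cost_matrix(
            np.array([t.position for t in predicted]),
            np.array(det_pos),
            cfg.dummy_cost,
        )
        assignment = hungarian_assign(cm)
    else:
        assignment = Assignment(
            pairs=[],
            unmatched_workers=list(range(len(predicted))),
            unmatched_jobs=list(range(len(det_pos))),
            total_cost=0.0,
        )

    if cfg.use_heading_check:
        accepted, rejected = heading_check(
            assignment,
            [t.heading for t in predicted],
            det_head,
            cfg.heading_tolerance,
        )
    else:
        accepted, rejected = list(assignment.pairs), []

    # pool rejected-pair members with the already-unmatched and re-match
    # greedily on pre-prediction positions
    pool_w = sorted({w for w, _ in rejected} | set(assignment.unmatched_workers))
    pool_j = sorted({j for _, j in rejected} | set(assignment.unmatched_jobs))
    if pool_w and pool_j:
        cm2 = build_cost_matrix(
            np.array([pre_positions[w] for w in pool_w]),
            np.array([det_pos[j] for j in pool_j]),
            cfg.dummy_cost,
        )
        repair = closest_neighbor_assign(cm2)
        for wi, ji in repair.pairs:
            if cm2.costs[wi, ji] <= cfg.gate:
                accepted.append((pool_w[wi], pool_j[ji]))
    matched_w = {w for w, _ in accepted}
    matched_j = {j for _, j in accepted}

    out: list[TrackerState] = []
    det_of_worker = dict(accepted)
    for w, pred in enumerate(predicted):
        if w in matched_w:
            j = det_of_worker[w]
            upd = kf_update(pred, det_pos[j], cfg.r_sd)
            heading = det_head[j] if det_head[j] is not None else pred.heading
            out.append(
                replace(
                    upd, heading=heading, age=pred.age + 1, missed=0, matched=True
                )
            )
        else:
            if pred.missed + 1 > cfg.max_missed:
                continue  # retired
            out.append(
                replace(pred, age=pred.age + 1, missed=pred.missed + 1, matched=False)
            )
    for j, pos in enumerate(det_pos):
        if j not in matched_j:
            t = new_tracker(next_id, pos, det_head[j])
            next_id += 1
            out.append(t)
    return out
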