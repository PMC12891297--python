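"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC kernel: multinomial NUTS (progressive,
biased trajectory sampling) with the classic termination criterion, a
three-window warmup (step size only, mass-matrix accumulation, step size
again), and divergence tracking.  Everything is driven by a single
``logp_grad(theta) -> (float, ndarray)`` callable, so the kernel is generic
and testable against analytically known targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_chain", "ChainDiagnostics"]

#: Energy error beyond which a trajectory is declared divergent.
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainDiagnostics:
    step_size: float
    n_divergent: int
    mean_accept: float
    max_depth_hits: int


def _leapfrog(logp_grad, theta, r, grad, eps, minv):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * minv * r1
    logp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, logp1, grad1


def _kinetic(r, minv):
    return 0.5 * float(np.dot(r * minv, r))


class _Tree:
    """One NUTS trajectory tree, built by recursive doubling."""

    __slots__ = (
        "logp_grad", "eps", "minv", "h0", "rng",
        "divergent", "sum_accept", "n_leaves",
    )

    def __init__(self, logp_grad, eps, minv, h0, rng):
        self.logp_grad = logp_grad
        self.eps = eps
        self.minv = minv
        self.h0 = h0
        self.rng = rng
        self.divergent = False
        self.sum_accept = 0.0
        self.n_leaves = 0

    def build(self, theta, r, grad, direction, depth):
        """Returns (theta-, r-, grad-, theta+, r+, grad+, proposal, logp_prop,
        log_weight, ok)."""
        if depth == 0:
            t1, r1, logp1, g1 = _leapfrog(
                self.logp_grad, theta, r, grad, direction * self.eps, self.minv
            )
            h1 = -logp1 + _kinetic(r1, self.minv)
            dh = h1 - self.h0
            if not np.isfinite(dh) or dh > DIVERGENCE_THRESHOLD:
                self.divergent = True
                return t1, r1, g1, t1, r1, g1, t1, logp1, -np.inf, False
            self.sum_accept += float(np.exp(min(0.0, -dh)))
            self.n_leaves += 1
            return t1, r1, g1, t1, r1, g1, t1, logp1, -dh, True

        out1 = self.build(theta, r, grad, direction, depth - 1)
        tm, rm, gm, tp, rp, gp, prop, logp_prop, lw1, ok = out1
        if not ok:
            return out1
        if direction == 1:
            out2 = self.build(tp, rp, gp, direction, depth - 1)
            _, _, _, tp, rp, gp, prop2, logp2, lw2, ok2 = out2
        else:
            out2 = self.build(tm, rm, gm, direction, depth - 1)
            tm, rm, gm = out2[0], out2[1], out2[2]
            prop2, logp2, lw2, ok2 = out2[6], out2[7], out2[8], out2[9]
        if not ok2:
            return tm, rm, gm, tp, rp, gp, prop, logp_prop, lw1, False
        # multinomial merge of the two subtrees
        lw = np.logaddexp(lw1, lw2)
        if np.log(self.rng.random()) < lw2 - lw:
            prop, logp_prop = prop2, logp2
        ok = _no_uturn(tm, rm, tp, rp, self.minv)
        return tm, rm, gm, tp, rp, gp, prop, logp_prop, lw, ok


def _no_uturn(theta_minus, r_minus, theta_plus, r_plus, minv):
    dt = theta_plus - theta_minus
    return (np.dot(dt, minv * r_minus) >= 0) and (np.dot(dt, minv * r_plus) >= 0)


def _find_initial_step(logp_grad, theta, minv, rng):
    eps = 1.0
    logp0, grad0 = logp_grad(theta)
    r0 = rng.standard_normal(theta.size) / np.sqrt(minv)
    h0 = -logp0 + _kinetic(r0, minv)
    _, r1, logp1, _ = _leapfrog(logp_grad, theta, r0, grad0, eps, minv)
    dh = (-logp1 + _kinetic(r1, minv)) - h0
    if not np.isfinite(dh):
        dh = np.inf
    direction = 1 if dh < np.log(2.0) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(logp_grad, theta, r0, grad0, eps, minv)
        dh = (-logp1 + _kinetic(r1, minv)) - h0
        if not np.isfinite(dh):
            dh = np.inf
        if (direction == 1 and dh >= np.log(2.0)) or (direction == -1 and dh <= np.log(2.0)):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target accept rate."""

    def __init__(self, eps0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0

    def update(self, accept):
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)


def sample_chain(
    logp_grad,
    theta0: np.ndarray,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
):
    """Run one NUTS chain; returns (draws, ChainDiagnostics).

    ``draws`` has shape ``(n_iter - warmup, dim)`` — the post-warmup positions
    in the order generated.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    minv = np.ones(dim)  # inverse mass (diagonal)

    eps = _find_initial_step(logp_grad, theta, minv, rng)
    da = _DualAveraging(eps, target=target_accept)

    # Stan-style warmup: fast start (step size only), expanding slow windows
    # each ending in a mass-matrix update, fast tail (step size only).
    fast_start = min(75, max(1, warmup // 5))
    fast_end = min(50, max(1, warmup // 10))
    window_ends = []
    pos, width = fast_start, 25
    while pos + width < warmup - fast_end:
        if pos + 3 * width >= warmup - fast_end:
            width = warmup - fast_end - pos  # absorb the remainder
        window_ends.append(pos + width)
        pos += width
        width *= 2
    if not window_ends and warmup > fast_start + fast_end + 2:
        window_ends = [warmup - fast_end]
    var_count = 0
    var_mean = np.zeros(dim)
    var_m2 = np.zeros(dim)

    draws = np.empty((n_iter - warmup, dim))
    n_div = 0
    max_depth_hits = 0
    accepts = []

    logp, grad = logp_grad(theta)
    for it in range(n_iter):
        r0 = rng.standard_normal(dim) / np.sqrt(minv)
        h0 = -logp + _kinetic(r0, minv)
        tree = _Tree(logp_grad, eps, minv, h0, rng)
        tm = tp = theta
        rm = rp = r0
        gm = gp = grad
        prop, logp_prop = theta, logp
        lw_total = 0.0  # weight of the initial point
        for depth in range(max_treedepth):
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                _, _, _, tp, rp, gp, p2, lp2, lw2, ok = tree.build(tp, rp, gp, 1, depth)
            else:
                tm, rm, gm, _, _, _, p2, lp2, lw2, ok = tree.build(tm, rm, gm, -1, depth)
            if tree.divergent or not ok:
                break  # invalid subtree: discard its proposal entirely
            # biased progressive sampling: favour the new subtree
            if np.log(rng.random()) < lw2 - lw_total:
                prop, logp_prop = p2, lp2
            lw_total = np.logaddexp(lw_total, lw2)
            if not _no_uturn(tm, rm, tp, rp, minv):
                break
        else:
            max_depth_hits += 1
        if tree.divergent and it >= warmup:
            n_div += 1
        theta, logp = prop, logp_prop
        _, grad = logp_grad(theta)

        accept = tree.sum_accept / max(tree.n_leaves, 1)
        accepts.append(accept)
        if it < warmup:
            eps = da.update(accept)
            in_slow = window_ends and fast_start <= it < window_ends[-1]
            if in_slow:
                var_count += 1
                delta = theta - var_mean
                var_mean += delta / var_count
                var_m2 += delta * (theta - var_mean)
            if window_ends and it == window_ends[0] - 1:
                window_ends.pop(0)
                if var_count > 1:
                    var = var_m2 / (var_count - 1)
                    # regularize toward unit scale, Stan-style
                    minv = (var_count / (var_count + 5.0)) * var + 1e-3 * (
                        5.0 / (var_count + 5.0)
                    )
                    eps = _find_initial_step(logp_grad, theta, minv, rng)
                    da = _DualAveraging(eps, target=target_accept)
                var_count = 0
                var_mean = np.zeros(dim)
                var_m2 = np.zeros(dim)
            if it == warmup - 1:
                eps = float(np.exp(da.log_eps_bar))
        else:
            draws[it - warmup] = theta

    diag = ChainDiagnostics(
        step_size=float(eps),
        n_divergent=n_div,
        mean_accept=float(np.mean(accepts[warmup:])) if n_iter > warmup else float("nan"),
        max_depth_hits=max_depth_hits,
    )
    return draws, diag
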