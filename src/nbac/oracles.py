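"""Brute-force reference implementations for auditing.

Every function here re-derives a documented formula with plain per-pixel
scalar loops (exhaustive searches, double-loop window maxima, literal
summation), deliberately avoiding the vectorized/scipy code paths of the
main modules.  They are slow and exist only to check the fast paths on small
instances — via ``nbac audit``, the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .band_operators import BandSpec
from .losses import ChanVeseParams, FocalParams, NBACWeights, OscParams

__all__ = [
    "heaviside_scalar",
    "signed_distance_bruteforce",
    "edge_extract_loop",
    "dilate_bruteforce",
    "gt_band_bruteforce",
    "ce_loop",
    "dice_loop",
    "focal_loop",
    "region_loop",
    "band_descriptors_loop",
    "nbac_band_loss_loop",
    "osc_loss_loop",
    "chan_vese_loop",
    "run_audit",
]

_CLIP = 1e-7
_SMOOTH = 1e-6


def heaviside_scalar(x: float, eps: float) -> float:
    import math

    return 0.5 * (1.0 + (2.0 / math.pi) * math.atan(x / eps))


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def signed_distance_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-opposite-pixel search (pixel-centre distances)."""
    mask = np.asarray(mask)
    coords = list(np.ndindex(mask.shape))
    ones = [c for c in coords if mask[c] == 1]
    zeros = [c for c in coords if mask[c] == 0]
    out = np.zeros(mask.shape, dtype=np.float64)
    for c in coords:
        others = zeros if mask[c] == 1 else ones
        best = min(
            sum((a - b) ** 2 for a, b in zip(c, o)) for o in others
        )
        d = np.sqrt(best)
        out[c] = d if mask[c] == 1 else -d
    return out


def _clamp(i: int, n: int) -> int:
    return min(max(i, 0), n - 1)


def edge_extract_loop(F: np.ndarray) -> np.ndarray:
    """Scalar-loop smoothed central-difference gradient magnitude."""
    F = np.asarray(F, dtype=np.float64)
    nd = F.ndim
    shape = F.shape
    smooth_w = {-1: 0.25, 0: 0.5, 1: 0.25}
    comps = []
    for a in range(nd):
        # central difference along axis a, replicate clamped
        d = np.zeros(shape)
        for idx in np.ndindex(shape):
            up = list(idx)
            dn = list(idx)
            up[a] = _clamp(idx[a] + 1, shape[a])
            dn[a] = _clamp(idx[a] - 1, shape[a])
            d[idx] = 0.5 * (F[tuple(up)] - F[tuple(dn)])
        # smooth along the remaining axes, in increasing axis order
        for b in range(nd):
            if b == a:
                continue
            s = np.zeros(shape)
            for idx in np.ndindex(shape):
                acc = 0.0
                for off, w in smooth_w.items():
                    j = list(idx)
                    j[b] = _clamp(idx[b] + off, shape[b])
                    acc += w * d[tuple(j)]
                s[idx] = acc
            d = s
        comps.append(d)
    out = np.zeros(shape)
    for idx in np.ndindex(shape):
        out[idx] = np.sqrt(sum(c[idx] ** 2 for c in comps))
    return out


def dilate_bruteforce(F: np.ndarray, B: int) -> np.ndarray:
    """Exhaustive window maximum over a B-wide square/cube (replicate pad)."""
    F = np.asarray(F, dtype=np.float64)
    r = B // 2
    out = np.zeros(F.shape)
    offsets = list(np.ndindex(*([2 * r + 1] * F.ndim)))
    for idx in np.ndindex(F.shape):
        best = -np.inf
        for off in offsets:
            j = tuple(
                _clamp(idx[a] + off[a] - r, F.shape[a]) for a in range(F.ndim)
            )
            best = max(best, F[j])
        out[idx] = best
    return out


def gt_band_bruteforce(y: np.ndarray, B: int):
    """Ground-truth narrow band via the loop operators; returns
    (band, indicator, inner, outer)."""
    band = dilate_bruteforce(edge_extract_loop(y), B)
    indicator = band > 0
    inner = indicator & (np.asarray(y) == 1)
    outer = indicator & (np.asarray(y) == 0)
    return band, indicator, inner, outer


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def ce_loop(P: np.ndarray, T: np.ndarray) -> float:
    total, n = 0.0, 0
    for idx in np.ndindex(P.shape):
        p = min(max(P[idx], _CLIP), 1 - _CLIP)
        total += -(T[idx] * np.log(p) + (1 - T[idx]) * np.log(1 - p))
        n += 1
    return total / n


def dice_loop(P: np.ndarray, T: np.ndarray) -> float:
    num, den = 0.0, 0.0
    for idx in np.ndindex(P.shape):
        num += P[idx] * T[idx]
        den += P[idx] + T[idx]
    return 1.0 - (2 * num + _SMOOTH) / (den + _SMOOTH)


def focal_loop(P: np.ndarray, T: np.ndarray, params: FocalParams) -> float:
    total, n = 0.0, 0
    for idx in np.ndindex(P.shape):
        p = min(max(P[idx], _CLIP), 1 - _CLIP)
        total += (1 - p) ** params.gamma * T[idx] * np.log(p)
        total += p**params.gamma * (1 - T[idx]) * np.log(1 - p)
        n += 1
    return -params.alpha * total / n


def region_loop(P: np.ndarray, T: np.ndarray) -> float:
    """P, T are (K, *grid)."""
    K = P.shape[0]
    total, n = 0.0, 0
    for idx in np.ndindex(P.shape[1:]):
        for c in range(K):
            p = min(max(P[(c,) + idx], _CLIP), 1 - _CLIP)
            total += -T[(c,) + idx] * np.log(p)
        n += 1
    return total / n


def band_descriptors_loop(p: np.ndarray, y: np.ndarray, B: int, mode: str):
    band, indicator, inner, outer = gt_band_bruteforce(y, B)
    if mode == "two_sided":
        ins = [p[i] for i in np.ndindex(p.shape) if inner[i]]
        outs = [p[i] for i in np.ndindex(p.shape) if outer[i]]
        return sum(ins) / len(ins), sum(outs) / len(outs)
    num_in = num_out = w_in = w_out = 0.0
    for i in np.ndindex(p.shape):
        num_in += p[i] * band[i]
        w_in += band[i]
        num_out += p[i] * (1 - band[i])
        w_out += 1 - band[i]
    return num_in / w_in, num_out / w_out


def nbac_band_loss_loop(
    p: np.ndarray,
    F_LC: np.ndarray,
    F_LN: np.ndarray,
    y: np.ndarray,
    B: int,
    w: NBACWeights,
) -> float:
    band, indicator, inner, outer = gt_band_bruteforce(y, B)
    length = 0.0
    for i in np.ndindex(F_LC.shape):
        length += abs(F_LC[i])
    length = w.mu * length / F_LC.size
    b_in, b_out = band_descriptors_loop(p, y, B, w.band_mode)
    e_in = e_out = 0.0
    if w.band_mode == "two_sided":
        n_in = n_out = 0
        for i in np.ndindex(p.shape):
            if inner[i]:
                e_in += (p[i] - b_in) ** 2
                n_in += 1
            if outer[i]:
                e_out += (p[i] - b_out) ** 2
                n_out += 1
        e_in = w.lambda_in * e_in / n_in
        e_out = w.lambda_out * e_out / n_out
    elif w.band_mode == "band_vs_complement":
        w_in = w_out = 0.0
        for i in np.ndindex(p.shape):
            e_in += band[i] * (p[i] - b_in) ** 2
            w_in += band[i]
            e_out += (1 - band[i]) * (p[i] - b_out) ** 2
            w_out += 1 - band[i]
        e_in = w.lambda_in * e_in / w_in
        e_out = w.lambda_out * e_out / w_out
    else:  # gated_domain
        for i in np.ndindex(p.shape):
            e_in += (p[i] * F_LN[i] - b_in) ** 2
            e_out += (p[i] * F_LN[i] - b_out) ** 2
        e_in = w.lambda_in * e_in / p.size
        e_out = w.lambda_out * e_out / p.size
    return length + e_in + e_out


def osc_loss_loop(P: np.ndarray, T: np.ndarray, params: OscParams) -> float:
    l1 = region_loop(P, T)
    total = params.alpha * l1
    if params.beta == 0 and params.eta == 0:
        return total
    band_terms = []
    for c in range(1, T.shape[0]):
        y = T[c]
        if y.min() == y.max():
            continue
        band, indicator, inner, outer = gt_band_bruteforce(y, params.B)
        if not indicator.any() or not inner.any() or not outer.any():
            continue
        p = P[c]
        ins = [p[i] for i in np.ndindex(p.shape) if inner[i]]
        outs = [p[i] for i in np.ndindex(p.shape) if outer[i]]
        b_minus, b_plus = sum(ins) / len(ins), sum(outs) / len(outs)
        hard = (p > 0.5).astype(float)
        phi = (
            signed_distance_bruteforce(hard)
            if 0 < hard.sum() < hard.size
            else signed_distance_bruteforce(y)
        )
        grad_phi = edge_extract_loop(phi)
        l2 = l3 = 0.0
        n_band = 0
        for i in np.ndindex(p.shape):
            if not indicator[i]:
                continue
            h = heaviside_scalar(phi[i], params.epsilon)
            l2 += params.lambda1 * (p[i] - b_minus) ** 2 * h
            l2 += params.lambda2 * (p[i] - b_plus) ** 2 * (1 - h)
            l3 += grad_phi[i]
            n_band += 1
        band_terms.append(params.beta * l2 / n_band + params.eta * l3 / n_band)
    if band_terms:
        total += sum(band_terms) / len(band_terms)
    return total


def chan_vese_loop(I: np.ndarray, phi: np.ndarray, params: ChanVeseParams) -> float:
    ins = [I[i] for i in np.ndindex(I.shape) if phi[i] > 0]
    outs = [I[i] for i in np.ndindex(I.shape) if phi[i] < 0]
    c1, c2 = sum(ins) / len(ins), sum(outs) / len(outs)
    fit = 0.0
    for i in np.ndindex(I.shape):
        if phi[i] > 0:
            fit += params.lambda1 * (I[i] - c1) ** 2
        elif phi[i] < 0:
            fit += params.lambda2 * (I[i] - c2) ** 2
    length = 0
    for i in np.ndindex(I.shape):
        for a in range(I.ndim):
            j = list(i)
            j[a] += 1
            if j[a] >= I.shape[a]:
                continue
            pi, pj = phi[i], phi[tuple(j)]
            if (pi > 0 and pj < 0) or (pi < 0 and pj > 0):
                length += 1
    area = len(ins)
    return fit + params.mu * length + params.nu * area


# ---------------------------------------------------------------------------
# audit entry point
# ---------------------------------------------------------------------------


def run_audit(seed: int = 0, n_instances: int = 10) -> dict:
    """Compare fast implementations against every oracle on random instances."""
    from . import band_operators as bo
    from . import losses as ls

    rng = np.random.default_rng(seed)
    report: dict[str, dict] = {}

    def record(name, devs):
        dev = float(np.max(devs)) if len(devs) else float("nan")
        report[name] = {"ok": bool(dev < 1e-6), "max_dev": dev}

    spec = BandSpec(B=3)

    devs = []
    for _ in range(n_instances):
        x = rng.normal(0, 3, size=(6, 6))
        eps = rng.uniform(0.1, 2.0)
        ref = np.vectorize(lambda v: heaviside_scalar(v, eps))(x)
        devs.append(np.abs(bo.heaviside_smooth(x, eps) - ref).max())
    record("heaviside_smooth", devs)

    devs = []
    for _ in range(n_instances):
        m = (rng.random((8, 8)) < 0.4).astype(float)
        if m.min() == m.max():
            continue
        devs.append(np.abs(bo.signed_distance(m) - signed_distance_bruteforce(m)).max())
    record("signed_distance", devs)

    devs = []
    for _ in range(n_instances):
        F = rng.random((9, 9))
        devs.append(np.abs(bo.edge_extract(F, spec) - edge_extract_loop(F)).max())
    record("edge_extract", devs)

    devs = []
    for _ in range(n_instances):
        F = rng.random((10, 10))
        devs.append(np.abs(bo.dilate_band(F, BandSpec(B=5)) - dilate_bruteforce(F, 5)).max())
    record("dilate_band", devs)

    devs = []
    for _ in range(n_instances):
        P, T = rng.random((5, 5)), (rng.random((5, 5)) < 0.5).astype(float)
        devs.append(abs(ls.ce_loss(P, T) - ce_loop(P, T)))
        devs.append(abs(ls.dice_loss(P, T) - dice_loop(P, T)))
        fp = FocalParams(alpha=0.25, gamma=2.0)
        devs.append(abs(ls.focal_loss(P, T, fp) - focal_loop(P, T, fp)))
    record("pixel_losses", devs)

    devs = []
    for _ in range(n_instances):
        y = np.zeros((10, 10))
        y[3:7, 2:8] = 1
        p = rng.random((10, 10))
        flc, fln = rng.random((10, 10)), rng.random((10, 10))
        for mode in ("two_sided", "band_vs_complement", "gated_domain"):
            w = NBACWeights(band_mode=mode)
            devs.append(
                abs(
                    ls.nbac_band_loss(p, flc, fln, y, spec, w)
                    - nbac_band_loss_loop(p, flc, fln, y, spec.B, w)
                )
            )
    record("nbac_band_loss", devs)

    devs = []
    for _ in range(n_instances):
        I = rng.random((8, 8))
        phi = rng.normal(size=(8, 8))
        cv = ChanVeseParams()
        devs.append(abs(ls.chan_vese_energy(I, phi, cv) - chan_vese_loop(I, phi, cv)))
    record("chan_vese", devs)

    return report
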