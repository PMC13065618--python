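"""Independent, deliberately plain re-implementation of the descriptor suite.

Used as the dual-implementation oracle: straightforward loops and explicit
arithmetic, sharing no helpers with the package code path.  Keep this file
boring on purpose.
"""

from __future__ import annotations

import math


def _mean(vals):
    return sum(vals) / len(vals)


def _median(vals):
    s = sorted(vals)
    n = len(s)
    mid = n // 2
    if n % 2 == 1:
        return s[mid]
    return 0.5 * (s[mid - 1] + s[mid])


def _sd(vals):
    if len(vals) < 2:
        return float("nan")
    m = _mean(vals)
    return math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))


def _vel_bin(v):
    if v < 500.0:
        return 0
    if v < 1000.0:
        return 1
    if v < 1500.0:
        return 2
    return 3


def _acc_bin(a):
    if a < -5000.0:
        return 0
    if a < 0.0:
        return 1
    if a < 5000.0:
        return 2
    return 3


V_TAGS = ["0_500", "500_1000", "1000_1500", "1500_inf"]
A_TAGS = ["minf_m5000", "m5000_0", "0_5000", "5000_inf"]
PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def reference_features(rec, epsilon: float = 0.0) -> dict[str, float]:
    """Per-leukocyte-then-population descriptor suite, computed the long way."""
    mean_abs_v = []
    mean_abs_a = []
    mean_signed_a = []
    n_pos_list = []
    n_neg_list = []
    for tr in rec.tracks:
        if len(tr.points) < 3:
            continue
        ts = [p.t for p in tr.points]
        xs = [p.x for p in tr.points]
        vs = []
        for i in range(len(xs) - 1):
            vs.append((xs[i + 1] - xs[i]) / (ts[i + 1] - ts[i]))
        accs = []
        for i in range(len(vs) - 1):
            accs.append((vs[i + 1] - vs[i]) / (ts[i + 1] - ts[i]))
        mean_abs_v.append(_mean([abs(v) for v in vs]))
        mean_abs_a.append(_mean([abs(a) for a in accs]) if accs else 0.0)
        mean_signed_a.append(_mean(accs) if accs else 0.0)
        npos = nneg = 0
        for i in range(len(vs) - 1):
            dv = vs[i + 1] - vs[i]
            if dv > epsilon:
                npos += 1
            elif dv < -epsilon:
                nneg += 1
        n_pos_list.append(npos)
        n_neg_list.append(nneg)

    out: dict[str, float] = {}
    out["v_ave"] = _mean(mean_abs_v)
    out["v_med"] = _median(mean_abs_v)
    out["a_ave"] = _mean(mean_abs_a)
    out["a_med"] = _median(mean_signed_a)

    for b in range(4):
        sel = [v for v in mean_abs_v if _vel_bin(v) == b]
        out[f"v_{V_TAGS[b]}"] = _mean(sel) if sel else 0.0
        out[f"N_v_{V_TAGS[b]}"] = float(len(sel))
        sela = [a for a in mean_signed_a if _acc_bin(a) == b]
        out[f"a_{A_TAGS[b]}"] = _mean(sela) if sela else 0.0
        out[f"N_a_{A_TAGS[b]}"] = float(len(sela))

    out["ratio_v_a_ave"] = out["v_ave"] / out["a_ave"] if out["a_ave"] != 0 else float("nan")
    out["ratio_v_a_med"] = out["v_med"] / out["a_med"] if out["a_med"] != 0 else float("nan")
    out["prod_v_a_ave"] = out["v_ave"] * out["a_ave"]
    out["prod_v_a_med"] = out["v_med"] * out["a_med"]

    out["R_pos"] = _mean([float(v) for v in n_pos_list])
    out["R_neg"] = _mean([float(v) for v in n_neg_list])
    out["R_ratio"] = out["R_pos"] / out["R_neg"] if out["R_neg"] != 0 else float("nan")

    out["s_vx"] = _sd(mean_abs_v)
    out["s_ax"] = _sd(mean_signed_a)
    sax = out["s_ax"]
    out["ratio_s_vx_s_ax"] = out["s_vx"] / sax if sax == sax and sax != 0 else float("nan")
    out["prod_s_vx_s_ax"] = out["s_vx"] * out["s_ax"]
    svx = out["s_vx"]
    out["ratio_v_ave_s_vx"] = out["v_ave"] / svx if svx == svx and svx != 0 else float("nan")
    out["ratio_a_ave_s_ax"] = out["a_ave"] / sax if sax == sax and sax != 0 else float("nan")

    for i, j in PAIRS:
        out[f"prod_v_{V_TAGS[i]}_x_{V_TAGS[j]}"] = out[f"v_{V_TAGS[i]}"] * out[f"v_{V_TAGS[j]}"]
        out[f"prod_a_{A_TAGS[i]}_x_{A_TAGS[j]}"] = out[f"a_{A_TAGS[i]}"] * out[f"a_{A_TAGS[j]}"]
    return out


def reference_wilks_lambda(X, labels) -> float:
    """det(W)/det(T) computed with explicit loops (brute-force oracle)."""
    import numpy as np

    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n, p = X.shape
    grand = [sum(X[i, j] for i in range(n)) / n for j in range(p)]
    T = [[sum((X[i, a] - grand[a]) * (X[i, b] - grand[b]) for i in range(n))
          for b in range(p)] for a in range(p)]
    W = [[0.0] * p for _ in range(p)]
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        gm = [sum(X[i, j] for i in idx) / len(idx) for j in range(p)]
        for a in range(p):
            for b in range(p):
                W[a][b] += sum((X[i, a] - gm[a]) * (X[i, b] - gm[b]) for i in idx)
    return float(np.linalg.det(np.array(W)) / np.linalg.det(np.array(T)))


def svd_varimax(loadings, tol: float = 1e-10, max_iter: int = 1000):
    """Kaiser's SVD-based varimax (row-normalized), independent of the
    pairwise-rotation algorithm under test."""
    import numpy as np

    L = np.array(loadings, dtype=float)
    p, m = L.shape
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    R = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p))
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return (A @ R) * h[:, None]
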