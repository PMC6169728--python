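"""Thresholds and polychoric / polyserial correlations.

Ordinal items are modelled as discretized standard-normal latent responses:
an observed category k means the latent response fell between thresholds
tau_k and tau_{k+1}.  Correlations are estimated by two-step maximum
likelihood (thresholds fixed at the inverse-normal of the cumulative
margins, then the latent correlation maximizes the bivariate-normal cell /
conditional likelihood), which is the estimator behind standard
ordinal-data SEM workflows.

Besides point estimates the module computes per-observation *influence*
values for every estimated correlation.  These linearize the estimator,
s_k ~= sigma_k + mean_i(u_ik), and are what the model-fitting layer uses
for DWLS weights, robust test-statistic scaling and family-clustered
sandwich standard errors.  The influence of a two-step estimate accounts
for the sampling variability of the estimated thresholds (and, for
polyserial, of the standardization of the continuous variable) via the
delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

__all__ = [
    "ThresholdSet",
    "PolychoricEstimate",
    "PolychoricMatrix",
    "bvn_cdf",
    "estimate_thresholds",
    "polychoric",
    "polyserial",
    "mixed_correlation_matrix",
]

_CLIP = 0.999
_INF = 8.5  # effective infinity on the standard-normal scale

# Gauss-Legendre nodes/weights (half rules, as in Genz's BVND)
_GL = {
    6: (
        np.array([0.9324695142031521, 0.6612093864662645, 0.2386191860831969]),
        np.array([0.1713244923791704, 0.3607615730481386, 0.4679139345726910]),
    ),
    12: (
        np.array([0.9815606342467192, 0.9041172563704749, 0.7699026741943047,
                  0.5873179542866175, 0.3678314989981802, 0.1252334085114689]),
        np.array([0.04717533638651183, 0.1069393259953184, 0.1600783285433462,
                  0.2031674267230659, 0.2334925365383548, 0.2491470458134028]),
    ),
    20: (
        np.array([0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
                  0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
                  0.5108670019508271, 0.3737060887154195, 0.2277858511416451,
                  0.07652652113349734]),
        np.array([0.01761400713915212, 0.04060142980038694, 0.06267204833410907,
                  0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
                  0.1316886384491766, 0.1420961093183820, 0.1491729864726037,
                  0.1527533871307258]),
    ),
}


def _bvnu(h, k, r: float):
    """Upper probability P(X > h, Y > k), vectorized in h, k (Genz BVND)."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    h = h.copy()
    k = k.copy()
    if abs(r) < 0.3:
        nodes, weights = _GL[6]
    elif abs(r) < 0.75:
        nodes, weights = _GL[12]
    else:
        nodes, weights = _GL[20]

    if abs(r) <= 0.925:
        bvn = np.zeros_like(h)
        if r != 0.0:
            hk = h * k
            hs = (h * h + k * k) / 2.0
            asr = np.arcsin(r)
            sn = np.sin(asr * np.concatenate([(1.0 - nodes), (1.0 + nodes)]) / 2.0)
            w2 = np.concatenate([weights, weights])
            sn_sh = sn.reshape(sn.shape + (1,) * h.ndim)
            w_sh = w2.reshape(w2.shape + (1,) * h.ndim)
            bvn = np.sum(
                w_sh * np.exp((sn_sh * hk - hs) / (1.0 - sn_sh * sn_sh)), axis=0
            )
            bvn = bvn * asr / (4.0 * np.pi)
        return np.clip(bvn + ndtr(-h) * ndtr(-k), 0.0, 1.0)

    # |r| > 0.925: transformed integrand near the singular correlation
    twopi = 2.0 * np.pi
    if r < 0.0:
        k = -k
    hk = h * k
    bvn = np.zeros_like(h)
    if abs(r) < 1.0:
        a_s = (1.0 - r) * (1.0 + r)
        a = np.sqrt(a_s)
        bs = (h - k) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr = -(bs / a_s + hk) / 2.0
        m = asr > -100.0
        bvn = np.where(
            m,
            a * np.exp(np.where(m, asr, 0.0))
            * (1.0 - c * (bs - a_s) * (1.0 - d * bs / 5.0) / 3.0
               + c * d * a_s * a_s / 5.0),
            0.0,
        )
        m2 = -hk < 100.0
        b = np.sqrt(bs)
        sp = np.sqrt(twopi) * ndtr(-b / a)
        bvn = bvn - np.where(
            m2,
            np.exp(np.where(m2, -hk / 2.0, 0.0)) * sp * b
            * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0),
            0.0,
        )
        a = a / 2.0
        xs_all = (a * np.concatenate([(1.0 - nodes), (1.0 + nodes)])) ** 2
        w_all = np.concatenate([weights, weights])
        for xs, w in zip(xs_all, w_all):
            rs = np.sqrt(1.0 - xs)
            asr1 = -(bs / xs + hk) / 2.0
            m3 = asr1 > -100.0
            sp1 = 1.0 + c * xs * (1.0 + d * xs)
            ep = np.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
            bvn = bvn + np.where(
                m3, a * w * np.exp(np.where(m3, asr1, 0.0)) * (ep - sp1), 0.0
            )
        bvn = -bvn / twopi
    if r > 0.0:
        bvn = bvn + ndtr(-np.maximum(h, k))
    else:
        bvn = -bvn
        gt = k > h
        bvn = bvn + np.where(gt, ndtr(k) - ndtr(h), 0.0)
    return np.clip(bvn, 0.0, 1.0)


def bvn_cdf(x, y, rho: float):
    """P(X <= x, Y <= y) under a standard bivariate normal with correlation rho.

    Vectorized in x and y (broadcast together); rho is a scalar in (-1, 1).
    """
    rho = float(np.clip(rho, -_CLIP, _CLIP))
    x = np.clip(np.asarray(x, dtype=float), -_INF, _INF)
    y = np.clip(np.asarray(y, dtype=float), -_INF, _INF)
    return _bvnu(-x, -y, rho)


def _bvn_pdf(x, y, rho: float):
    """Standard bivariate normal density, zero at infinite arguments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = np.broadcast_arrays(x, y)
    s = 1.0 - rho * rho
    finite = (np.abs(x) < _INF) & (np.abs(y) < _INF)
    xf = np.where(finite, x, 0.0)
    yf = np.where(finite, y, 0.0)
    dens = np.exp(-(xf * xf - 2.0 * rho * xf * yf + yf * yf) / (2.0 * s)) / (
        2.0 * np.pi * np.sqrt(s)
    )
    return np.where(finite, dens, 0.0)


# ----------------------------------------------------------------------
# thresholds


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered cutpoints of one ordinal variable on the standard-normal scale."""

    item: str
    taus: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.taus, dtype=float)
        if len(t) and (not np.all(np.isfinite(t)) or np.any(np.diff(t) <= 0)):
            raise ValueError(f"{self.item}: thresholds must be finite and increasing")

    @property
    def cuts(self) -> np.ndarray:
        """Thresholds padded with -inf / +inf for cell-probability grids."""
        return np.concatenate([[-np.inf], self.taus, [np.inf]])


def estimate_thresholds(counts: Sequence[float], item: str = "?") -> ThresholdSet:
    """Thresholds from category counts: tau_k = Phi^-1(cumulative proportion).

    Every declared category must be non-empty; an empty category makes one
    threshold non-identified, in which case the caller should collapse
    categories or exclude the item.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 2:
        raise ValueError(f"{item}: need >= 2 categories")
    if np.any(counts <= 0):
        raise ValueError(
            f"{item}: empty category in declared coding; collapse categories "
            "or exclude the item"
        )
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return ThresholdSet(item=item, taus=tuple(stats.norm.ppf(cum)))


# ----------------------------------------------------------------------
# polychoric


@dataclass
class PolychoricEstimate:
    rho: float
    var: float  # asymptotic variance from observed information (rho step)
    n: int
    thresholds: tuple[ThresholdSet, ThresholdSet] | ThresholdSet | None = None
    boundary: bool = False


def _cell_probs(rho: float, cuts_x: np.ndarray, cuts_y: np.ndarray) -> np.ndarray:
    """Rectangle probabilities of the bivariate-normal cells."""
    cdf = bvn_cdf(cuts_x[:, None], cuts_y[None, :], rho)
    return np.maximum(cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1], 1e-300)


def _cell_dprobs(rho: float, cuts_x: np.ndarray, cuts_y: np.ndarray) -> np.ndarray:
    """d(cell probability)/d(rho) via the bivariate density (Plackett)."""
    dens = _bvn_pdf(cuts_x[:, None], cuts_y[None, :], rho)
    return dens[1:, 1:] - dens[:-1, 1:] - dens[1:, :-1] + dens[:-1, :-1]


def polychoric(table: np.ndarray | pd.DataFrame,
               item_x: str = "x", item_y: str = "y") -> PolychoricEstimate:
    """Two-step ML polychoric correlation from a two-way contingency table.

    Thresholds are fixed at the margin-implied values; the latent
    correlation maximizes the bivariate-normal cell likelihood.  The
    asymptotic variance is the inverse observed information of the profile
    likelihood in rho at the optimum.  Estimates at the +-0.999 boundary
    are clipped and flagged.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    n = tab.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    tx = estimate_thresholds(tab.sum(axis=1), item_x)
    ty = estimate_thresholds(tab.sum(axis=0), item_y)
    cx, cy = tx.cuts, ty.cuts

    def negll(r: float) -> float:
        return -float(np.sum(tab * np.log(_cell_probs(r, cx, cy))))

    res = optimize.minimize_scalar(
        negll, bounds=(-_CLIP, _CLIP), method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    boundary = abs(rho) >= _CLIP - 1e-6
    if boundary:
        warnings.warn(
            f"polychoric({item_x},{item_y}): estimate at the +-{_CLIP} boundary",
            RuntimeWarning,
        )
    # observed information by central second difference of the negative ll
    h = 1e-4
    r_lo, r_hi = max(rho - h, -_CLIP), min(rho + h, _CLIP)
    d2 = (negll(r_hi) - 2.0 * negll(rho) + negll(r_lo)) / ((r_hi - rho) * (rho - r_lo))
    var = 1.0 / d2 if d2 > 0 else np.inf
    return PolychoricEstimate(
        rho=rho, var=float(var), n=int(n), thresholds=(tx, ty), boundary=boundary
    )


def _contingency(x: np.ndarray, y: np.ndarray, kx: int, ky: int) -> np.ndarray:
    tab = np.zeros((kx, ky))
    np.add.at(tab, (x, y), 1.0)
    return tab


def _threshold_influence(codes: np.ndarray, counts: np.ndarray,
                         taus: np.ndarray) -> np.ndarray:
    """Influence of each estimated threshold: rows = observations."""
    n = len(codes)
    props = np.cumsum(counts)[:-1] / counts.sum()
    dens = stats.norm.pdf(taus)
    below = codes[:, None] <= np.arange(len(taus))[None, :]
    return (below - props[None, :]) / dens[None, :]


def polychoric_influence(
    x: np.ndarray, y: np.ndarray, est: PolychoricEstimate
) -> np.ndarray:
    """Per-observation influence of the two-step polychoric estimate.

    Delta-method linearization treating the margin-estimated thresholds as
    plug-in estimators: u_i = (psi_i + sum_c h_c u_{tau_c,i}) / H with
    psi the per-observation rho-score, H the average negative score
    derivative and h_c the cross-derivatives with the thresholds.
    """
    tx, ty = est.thresholds
    kx, ky = len(tx.taus) + 1, len(ty.taus) + 1
    tab = _contingency(x, y, kx, ky)
    n = len(x)
    rho = est.rho

    def score_table(taus_x: np.ndarray, taus_y: np.ndarray) -> np.ndarray:
        cx = np.concatenate([[-np.inf], taus_x, [np.inf]])
        cy = np.concatenate([[-np.inf], taus_y, [np.inf]])
        return _cell_dprobs(rho, cx, cy) / _cell_probs(rho, cx, cy)

    taus_x = np.asarray(tx.taus)
    taus_y = np.asarray(ty.taus)
    psi_cells = score_table(taus_x, taus_y)
    psi = psi_cells[x, y]

    # H = -(1/n) d/drho sum_i psi_i, numerically on the mean score
    h = 1e-4

    def mean_score(r: float) -> float:
        cx, cy = tx.cuts, ty.cuts
        return float(np.sum(tab * (_cell_dprobs(r, cx, cy) / _cell_probs(r, cx, cy)))) / n

    H = -(mean_score(rho + h) - mean_score(rho - h)) / (2.0 * h)
    if H <= 0:
        H = 1e-8

    corr = np.zeros(n)
    for which, taus, codes, counts in (
        ("x", taus_x, x, tab.sum(axis=1)),
        ("y", taus_y, y, tab.sum(axis=0)),
    ):
        u_tau = _threshold_influence(codes, counts, taus)
        for c in range(len(taus)):
            tp = taus.copy()
            tp[c] += h
            tm = taus.copy()
            tm[c] -= h
            if which == "x":
                sp = float(np.sum(tab * score_table(tp, taus_y)))
                sm = float(np.sum(tab * score_table(tm, taus_y)))
            else:
                sp = float(np.sum(tab * score_table(taus_x, tp)))
                sm = float(np.sum(tab * score_table(taus_x, tm)))
            h_c = (sp - sm) / (2.0 * h * n)
            corr += h_c * u_tau[:, c]
    return (psi + corr) / H


# ----------------------------------------------------------------------
# polyserial


def polyserial(
    ordinal: np.ndarray, continuous: np.ndarray, item: str = "?"
) -> tuple[PolychoricEstimate, np.ndarray]:
    """Two-step ML polyserial correlation and its influence values.

    The continuous variable is standardized in-sample; thresholds come from
    the ordinal margin; the latent correlation maximizes the conditional
    likelihood of the ordinal response given the continuous value.  Returns
    the estimate and the per-observation influence vector (threshold and
    standardization corrections included).
    """
    y = np.asarray(ordinal)
    xraw = np.asarray(continuous, dtype=float)
    if xraw.std() == 0.0:
        raise ValueError(f"{item}: continuous variable is constant")
    n = len(y)
    cats, codes = np.unique(y, return_inverse=True)
    if len(cats) < 2:
        raise ValueError(f"{item}: ordinal variable needs >= 2 observed categories")
    counts = np.bincount(codes, minlength=len(cats)).astype(float)
    ts = estimate_thresholds(counts, item)
    taus = np.asarray(ts.taus)
    mu, sd = xraw.mean(), xraw.std(ddof=0)

    def ll_vec(r: float, taus_: np.ndarray, mu_: float, sd_: float) -> np.ndarray:
        z = (xraw - mu_) / sd_
        s = np.sqrt(1.0 - r * r)
        cuts = np.concatenate([[-_INF * 2], taus_, [_INF * 2]])
        upper = (cuts[codes + 1] - r * z) / s
        lower = (cuts[codes] - r * z) / s
        return np.log(np.maximum(ndtr(upper) - ndtr(lower), 1e-300))

    def negll(r: float) -> float:
        return -float(np.sum(ll_vec(r, taus, mu, sd)))

    res = optimize.minimize_scalar(
        negll, bounds=(-_CLIP, _CLIP), method="bounded", options={"xatol": 1e-8}
    )
    rho = float(res.x)
    boundary = abs(rho) >= _CLIP - 1e-6

    h = 1e-4
    # per-observation rho-score and mean-score derivatives, all numeric
    psi = (ll_vec(rho + h, taus, mu, sd) - ll_vec(rho - h, taus, mu, sd)) / (2.0 * h)

    def mean_score(r: float, taus_: np.ndarray, mu_: float, sd_: float) -> float:
        return float(
            np.mean((ll_vec(r + h, taus_, mu_, sd_) - ll_vec(r - h, taus_, mu_, sd_))
                    / (2.0 * h))
        )

    H = -(mean_score(rho + h, taus, mu, sd) - mean_score(rho - h, taus, mu, sd)) / (
        2.0 * h
    )
    if H <= 0:
        H = 1e-8
    var = 1.0 / (n * H)

    corr = np.zeros(n)
    u_tau = _threshold_influence(codes, counts, taus)
    for c in range(len(taus)):
        tp = taus.copy()
        tp[c] += h
        tm = taus.copy()
        tm[c] -= h
        h_c = (mean_score(rho, tp, mu, sd) - mean_score(rho, tm, mu, sd)) / (2.0 * h)
        corr += h_c * u_tau[:, c]
    # standardization corrections: mu-hat and sd-hat are plug-ins too
    h_mu = (mean_score(rho, taus, mu + h, sd) - mean_score(rho, taus, mu - h, sd)) / (
        2.0 * h
    )
    h_sd = (mean_score(rho, taus, mu, sd + h) - mean_score(rho, taus, mu, sd - h)) / (
        2.0 * h
    )
    u_mu = xraw - mu
    u_sd = ((xraw - mu) ** 2 - sd * sd) / (2.0 * sd)
    corr += h_mu * u_mu + h_sd * u_sd

    influence = (psi + corr) / H
    est = PolychoricEstimate(
        rho=rho, var=float(var), n=n, thresholds=ts, boundary=boundary
    )
    return est, influence


# ----------------------------------------------------------------------
# mixed correlation matrix


@dataclass
class PolychoricMatrix:
    """Mixed polychoric / polyserial / Pearson correlation matrix.

    ``moment_index`` enumerates the fitted sample moments (ordinal-ordinal
    and ordinal-continuous pairs by default; continuous-continuous cells are
    retained in the matrix but treated as fixed).  ``influence`` is the
    n x n_moments linearization used for DWLS weights and sandwich errors;
    ``moment_var`` its implied sampling variance per moment.
    """

    labels: list[str]
    matrix: np.ndarray
    cell_types: dict[tuple[str, str], str]
    thresholds: dict[str, ThresholdSet]
    moment_index: list[tuple[int, int]]
    moment_var: np.ndarray
    influence: np.ndarray
    n: int
    repaired: bool = False

    @classmethod
    def from_correlations(
        cls,
        labels: Sequence[str],
        matrix: np.ndarray,
        n_ordinal: int,
        n: int,
        moment_var: float | np.ndarray = 1.0,
    ) -> "PolychoricMatrix":
        """Wrap a known correlation matrix as a moment object (no influence).

        Useful for fitting to exact model-implied matrices; weights default
        to 1 and no observation-level influence is available, so fits on
        such moments report discrepancies but not standard errors.
        """
        labels = list(labels)
        p_all = len(labels)
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (p_all, p_all):
            raise ValueError("matrix shape does not match labels")
        moment_index = [
            (i, j)
            for i in range(p_all)
            for j in range(i + 1, p_all)
            if i < n_ordinal  # skip continuous-continuous cells
        ]
        k = len(moment_index)
        mv = np.broadcast_to(np.asarray(moment_var, dtype=float), (k,)).copy()
        return cls(
            labels=labels,
            matrix=matrix,
            cell_types={},
            thresholds={},
            moment_index=moment_index,
            moment_var=mv,
            influence=np.empty((n, 0)),
            n=n,
        )

    def corr(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[ia, ib])

    @property
    def moment_values(self) -> np.ndarray:
        return np.array([self.matrix[i, j] for i, j in self.moment_index])

    def to_tsv(self, path) -> None:
        """Typed matrix file: header block (n, repair flag, thresholds,
        per-moment estimate type and sampling variance), then the matrix."""
        with open(path, "w") as fh:
            fh.write(f"# n\t{self.n}\n# repaired\t{int(self.repaired)}\n")
            for lab, ts in self.thresholds.items():
                fh.write("# thresholds\t" + lab + "\t"
                         + "\t".join(f"{t:.10g}" for t in ts.taus) + "\n")
            for k, (i, j) in enumerate(self.moment_index):
                a, b = self.labels[i], self.labels[j]
                ctype = self.cell_types.get((a, b), self.cell_types.get((b, a), "?"))
                fh.write(f"# moment\t{a}\t{b}\t{ctype}\t{self.moment_var[k]:.12g}\n")
            pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
                fh, sep="\t"
            )

    @classmethod
    def read_tsv(cls, path) -> tuple[pd.DataFrame, dict[str, ThresholdSet],
                                     pd.DataFrame, int]:
        """Read back matrix, thresholds, moment metadata and n.

        Observation-level influence values are not persisted; a reloaded
        matrix supports fitting with the stored weights but not
        cluster-robust inference.
        """
        thresholds: dict[str, ThresholdSet] = {}
        moment_rows = []
        n = 0
        header_rows = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                header_rows += 1
                parts = line[1:].strip().split("\t")
                if parts[0] == "n":
                    n = int(parts[1])
                elif parts[0] == "thresholds":
                    thresholds[parts[1]] = ThresholdSet(
                        item=parts[1], taus=tuple(float(t) for t in parts[2:])
                    )
                elif parts[0] == "moment":
                    moment_rows.append(
                        {"var_a": parts[1], "var_b": parts[2],
                         "type": parts[3], "variance": float(parts[4])}
                    )
        mat = pd.read_csv(path, sep="\t", skiprows=header_rows, index_col=0)
        moments = pd.DataFrame(moment_rows,
                               columns=["var_a", "var_b", "type", "variance"])
        return mat, thresholds, moments, n


def _nearest_psd(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.maximum(vals, floor)
    out = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def mixed_correlation_matrix(
    data: pd.DataFrame,
    ordinal: Sequence[str],
    continuous: Sequence[str] = (),
    min_pair_n: int = 50,
    psd_floor: float = 1e-6,
    sparse_warn: int = 5,
) -> PolychoricMatrix:
    """Assemble the sample-moment matrix for ordinal-indicator SEM.

    Polychoric correlations for ordinal x ordinal cells, polyserial for
    ordinal x continuous, Pearson for continuous x continuous.  Estimation
    is pairwise-complete with a minimum-n guard; influence entries of
    observations missing from a pair are zero and the pair's contribution
    is rescaled to the full n.  If the assembled matrix is not positive
    semidefinite it is repaired by eigenvalue flooring (flagged).
    """
    labels = list(ordinal) + list(continuous)
    if len(labels) < 2:
        raise ValueError("need at least two variables")
    p = len(labels)
    n = len(data)
    ord_set = set(ordinal)

    too_small = []
    for i in range(p):
        for j in range(i + 1, p):
            ok = data[labels[i]].notna() & data[labels[j]].notna()
            if ok.sum() < min_pair_n:
                too_small.append((labels[i], labels[j]))
    if too_small:
        raise ValueError(f"pairs below minimum n={min_pair_n}: {too_small}")

    # per-variable codes and thresholds
    codes: dict[str, np.ndarray] = {}
    thresholds: dict[str, ThresholdSet] = {}
    for lab in ordinal:
        col = data[lab]
        vals = col.dropna().to_numpy()
        cats = np.unique(vals)
        counts = np.array([(vals == c).sum() for c in cats], dtype=float)
        if np.any(counts < sparse_warn):
            warnings.warn(
                f"item {lab!r}: a category has fewer than {sparse_warn} "
                "endorsements; estimates may be unstable",
                RuntimeWarning,
            )
        thresholds[lab] = estimate_thresholds(counts, lab)
        code = np.full(n, -1, dtype=int)
        notna = col.notna().to_numpy()
        code[notna] = np.searchsorted(cats, col.to_numpy()[notna])
        codes[lab] = code

    mat = np.eye(p)
    cell_types: dict[tuple[str, str], str] = {}
    moment_index: list[tuple[int, int]] = []
    infl_cols: list[np.ndarray] = []

    for i in range(p):
        for j in range(i + 1, p):
            a, b = labels[i], labels[j]
            both_ord = a in ord_set and b in ord_set
            both_cont = a not in ord_set and b not in ord_set
            mask = (data[a].notna() & data[b].notna()).to_numpy()
            n_pair = int(mask.sum())
            if both_cont:
                xa = data[a].to_numpy(dtype=float)[mask]
                xb = data[b].to_numpy(dtype=float)[mask]
                r = float(np.corrcoef(xa, xb)[0, 1])
                mat[i, j] = mat[j, i] = r
                cell_types[(a, b)] = "pearson"
                continue
            if both_ord:
                xa = codes[a][mask]
                xb = codes[b][mask]
                tab = _contingency(xa, xb, len(thresholds[a].taus) + 1,
                                   len(thresholds[b].taus) + 1)
                est = polychoric(tab, a, b)
                u_pair = polychoric_influence(xa, xb, est)
                cell_types[(a, b)] = "polychoric"
            else:
                olab, clab = (a, b) if a in ord_set else (b, a)
                xo = codes[olab][mask]
                xc = data[clab].to_numpy(dtype=float)[mask]
                est, u_pair = polyserial(xo, xc, olab)
                cell_types[(a, b)] = "polyserial"
            mat[i, j] = mat[j, i] = est.rho
            u = np.zeros(n)
            u[mask] = u_pair * (n / n_pair)  # rescale pairwise-complete mean
            moment_index.append((i, j))
            infl_cols.append(u)

    influence = np.column_stack(infl_cols) if infl_cols else np.empty((n, 0))
    influence = influence - influence.mean(axis=0, keepdims=True)
    moment_var = (influence ** 2).sum(axis=0) / (n * n)

    repaired = False
    eigmin = np.linalg.eigvalsh(mat).min()
    if eigmin < psd_floor:
        mat = _nearest_psd(mat, psd_floor)
        repaired = True
        warnings.warn(
            f"correlation matrix not PSD (min eigenvalue {eigmin:.3g}); "
            "repaired by eigenvalue flooring",
            RuntimeWarning,
        )

    return PolychoricMatrix(
        labels=labels,
        matrix=mat,
        cell_types=cell_types,
        thresholds=thresholds,
        moment_index=moment_index,
        moment_var=moment_var,
        influence=influence,
        n=n,
        repaired=repaired,
    )
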