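"""Type-I and type-II functional divergence between subfamily clusters.

Type I (rate-shift divergence) follows the classic two-state mixture for
site-specific rates after duplication: with probability theta a site's
substitution rate is independent between the two clusters (state F1), with
probability 1 - theta it is shared (F0). Rates are Gamma(alpha, mean 1)
and the per-cluster minimum substitution counts (Fitch parsimony on the
cluster's own NJ subtree) are Poisson given rate x cluster tree length.
theta, alpha and the two tree-length scalars are estimated by maximum
likelihood (multi-start quasi-Newton); the LRT against theta = 0 is
referred to chi-square(1), and the per-site posterior of F1 is Q_k.

Type II (property-shift divergence) is a moments estimator: sites carrying
a between-cluster fixed difference whose amino-acid property class changes
(radical: charge/polarity partition) are in excess of the baseline
expected from within-cluster variation; theta_II is that excess as a
fraction of sites, and may legitimately come out negative. Sites with
Q_k above a threshold (default 0.9) are reported as divergence-related.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .phylogeny import build_nj, pairwise_distance

__all__ = [
    "DivergenceResult",
    "PROPERTY_CLASS",
    "is_radical",
    "site_substitution_counts",
    "estimate_theta1",
    "estimate_theta2",
    "divergence_report",
]

# charge/polarity partition used for radical vs conservative changes
PROPERTY_CLASS = {
    **{a: "nonpolar" for a in "AVLIMFWPG"},
    **{a: "polar" for a in "STNQYC"},
    **{a: "acidic" for a in "DE"},
    **{a: "basic" for a in "KRH"},
}


def is_radical(a: str, b: str) -> bool:
    """True when a substitution crosses property classes."""
    return PROPERTY_CLASS.get(a) != PROPERTY_CLASS.get(b)


# expected radical fraction for a uniformly random residue pair (class sizes)
_SIZES = Counter(PROPERTY_CLASS.values())
_P_RADICAL0 = 1.0 - sum(s * (s - 1) for s in _SIZES.values()) / (20 * 19)


@dataclass
class DivergenceResult:
    div_type: str  # "I" or "II"
    theta: float
    se: float
    lrt: float | None  # type I only
    p_value: float | None
    qk: np.ndarray  # per kept alignment column
    columns: list[int]  # 1-based alignment columns the qk refer to
    critical_sites: list[int] = field(default_factory=list)
    boundary: bool = False  # theta clipped at a bound
    note: str = ""

    def critical(self, threshold: float = 0.9) -> list[int]:
        return [c for c, q in zip(self.columns, self.qk) if q > threshold]


# ---------------------------------------------------------------------------
# per-site substitution counts (Fitch parsimony)


def _fitch_counts(aln_rows: list[str], tree) -> np.ndarray:
    """Minimum substitutions per column on a fixed tree; gaps are missing."""
    L = len(aln_rows[0])
    leaf_rows = {}
    for leaf in tree.leaf_node_iter():
        leaf_rows[leaf] = aln_rows[int(leaf.taxon.label)]
    counts = np.zeros(L, dtype=int)
    for col in range(L):
        changes = 0
        states: dict[int, frozenset | None] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                c = leaf_rows[node][col]
                states[id(node)] = None if c in "-.X" else frozenset(c)
                continue
            child_sets = [states[id(ch)] for ch in node.child_nodes()]
            child_sets = [s for s in child_sets if s is not None]
            if not child_sets:
                states[id(node)] = None
                continue
            state = child_sets[0]
            for s in child_sets[1:]:  # sequential Fitch fold (handles multifurcations)
                inter = state & s
                if inter:
                    state = inter
                else:
                    state = state | s
                    changes += 1
            states[id(node)] = state
        counts[col] = changes
    return counts


def _cluster_tree(sub_aln: dict[str, str]):
    """NJ tree of one cluster; taxa relabelled by row index for Fitch."""
    ids = list(sub_aln)
    relabelled = {str(i): sub_aln[g] for i, g in enumerate(ids)}
    dm = pairwise_distance(relabelled)
    if not np.isfinite(dm.d).all():
        d = dm.d.copy()
        finite_max = d[np.isfinite(d)].max(initial=1.0)
        d[~np.isfinite(d)] = 2.0 * finite_max
        dm.d = d
    return build_nj(dm), [relabelled[str(i)] for i in range(len(ids))]


def site_substitution_counts(
    alignment: dict[str, str],
    cluster_a: list[str],
    cluster_b: list[str],
    max_gap_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-column (x1, x2) minimum substitution counts for two clusters.

    Counts come from Fitch parsimony on each cluster's own NJ subtree.
    Columns whose gap fraction across both clusters exceeds
    ``max_gap_frac`` are excluded. Returns (x1, x2, kept 1-based columns).
    """
    for name, cluster in (("a", cluster_a), ("b", cluster_b)):
        if len(cluster) < 4:
            raise ValueError(
                f"cluster {name} has {len(cluster)} sequences; at least 4 required"
            )
    if set(cluster_a) & set(cluster_b):
        raise ValueError("clusters overlap")
    rows_all = [alignment[g] for g in (*cluster_a, *cluster_b)]
    L = len(rows_all[0])
    gap_frac = np.array(
        [sum(r[c] in "-." for r in rows_all) / len(rows_all) for c in range(L)]
    )
    kept = [c for c in range(L) if gap_frac[c] <= max_gap_frac]
    tree_a, rows_a = _cluster_tree({g: alignment[g] for g in cluster_a})
    tree_b, rows_b = _cluster_tree({g: alignment[g] for g in cluster_b})
    x1 = _fitch_counts(rows_a, tree_a)[kept]
    x2 = _fitch_counts(rows_b, tree_b)[kept]
    return x1, x2, [c + 1 for c in kept]


# ---------------------------------------------------------------------------
# type I: Poisson-gamma two-state mixture ML


def _log_p_shared(x1, x2, alpha, t1, t2):
    return (
        x1 * np.log(t1)
        + x2 * np.log(t2)
        - gammaln(x1 + 1)
        - gammaln(x2 + 1)
        + alpha * np.log(alpha)
        - gammaln(alpha)
        + gammaln(x1 + x2 + alpha)
        - (x1 + x2 + alpha) * np.log(t1 + t2 + alpha)
    )


def _log_p_indep(x, alpha, t):
    return (
        x * np.log(t)
        - gammaln(x + 1)
        + alpha * np.log(alpha)
        - gammaln(alpha)
        + gammaln(x + alpha)
        - (x + alpha) * np.log(t + alpha)
    )


def _loglik(theta, alpha, t1, t2, x1, x2):
    lp0 = _log_p_shared(x1, x2, alpha, t1, t2)
    lp1 = _log_p_indep(x1, alpha, t1) + _log_p_indep(x2, alpha, t2)
    if theta <= 0:
        return float(lp0.sum()), None
    if theta >= 1:
        return float(lp1.sum()), None
    stack = np.stack([np.log1p(-theta) + lp0, np.log(theta) + lp1])
    site_ll = logsumexp(stack, axis=0)
    qk = np.exp(np.log(theta) + lp1 - site_ll)
    return float(site_ll.sum()), qk


def _fit(x1, x2, theta_fixed=None, starts=(0.05, 0.25, 0.45, 0.65, 0.85)):
    def unpack(raw):
        if theta_fixed is None:
            theta = 1.0 / (1.0 + np.exp(-raw[0]))
            rest = raw[1:]
        else:
            theta = theta_fixed
            rest = raw
        alpha, t1, t2 = np.exp(np.clip(rest, -12, 12))
        return theta, alpha, t1, t2

    def negll(raw):
        theta, alpha, t1, t2 = unpack(raw)
        ll, _ = _loglik(theta, alpha, t1, t2, x1, x2)
        return -ll

    m1 = max(float(np.mean(x1)), 0.05)
    m2 = max(float(np.mean(x2)), 0.05)
    best = None
    start_list = starts if theta_fixed is None else (None,)
    for th0 in start_list:
        raw0 = [np.log(1.0), np.log(m1), np.log(m2)]
        if theta_fixed is None:
            raw0 = [np.log(th0 / (1 - th0))] + raw0
        res = minimize(negll, np.array(raw0), method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-10})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("type-I optimiser failed to converge from any start")
    return unpack(best.x), -best.fun


def _theta_se(x1, x2, theta, alpha, t1, t2) -> float:
    """SE from the observed information (central-difference Hessian)."""
    p = np.array([theta, alpha, t1, t2])
    h = np.maximum(np.abs(p) * 1e-4, 1e-6)

    def ll_at(q):
        th = min(max(q[0], 1e-9), 1 - 1e-9)
        return _loglik(th, max(q[1], 1e-9), max(q[2], 1e-9), max(q[3], 1e-9), x1, x2)[0]

    n = len(p)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(n)[i] * h[i]
            ej = np.eye(n)[j] * h[j]
            H[i, j] = H[j, i] = (
                ll_at(p + ei + ej) - ll_at(p + ei - ej)
                - ll_at(p - ei + ej) + ll_at(p - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        v = cov[0, 0]
        return float(np.sqrt(v)) if v > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")


def estimate_theta1(
    x1: np.ndarray, x2: np.ndarray, columns: list[int] | None = None,
    qk_threshold: float = 0.9,
) -> DivergenceResult:
    """ML estimate of the type-I divergence coefficient from site counts."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) != len(x2):
        raise ValueError("count vectors differ in length")
    if len(x1) < 50:
        raise ValueError("need at least 50 usable sites")
    columns = columns or list(range(1, len(x1) + 1))
    (theta, alpha, t1, t2), ll1 = _fit(x1, x2)
    (_, a0, t10, t20), ll0 = _fit(x1, x2, theta_fixed=0.0)
    ll1 = max(ll1, ll0)  # nested models: the alternative can never fit worse
    lrt = 2.0 * (ll1 - ll0)
    boundary = theta < 1e-4 or theta > 1 - 1e-4
    _, qk = _loglik(min(max(theta, 1e-9), 1 - 1e-9), alpha, t1, t2, x1, x2)
    if qk is None:
        qk = np.zeros(len(x1))
    se = _theta_se(x1, x2, theta, alpha, t1, t2)
    result = DivergenceResult(
        div_type="I",
        theta=float(np.clip(theta, 0.0, 1.0)),
        se=se,
        lrt=float(lrt),
        p_value=float(chi2.sf(lrt, df=1)),
        qk=qk,
        columns=columns,
        boundary=boundary,
    )
    result.critical_sites = result.critical(qk_threshold)
    return result


# ---------------------------------------------------------------------------
# type II: radical fixed-difference moments estimator


def _consensus(residues: list[str]) -> tuple[str, float]:
    counts = Counter(r for r in residues if r not in "-.X")
    if not counts:
        return "-", 0.0
    best = sorted(counts.items(), key=lambda t: (-t[1], t[0]))[0]
    return best[0], best[1] / sum(counts.values())


def estimate_theta2(
    alignment: dict[str, str],
    cluster_a: list[str],
    cluster_b: list[str],
    max_gap_frac: float = 0.5,
    fixation_freq: float = 0.75,
    qk_threshold: float = 0.9,
) -> DivergenceResult:
    """Moments estimate of the type-II divergence coefficient.

    A site shows a fixed difference when each cluster's consensus residue
    reaches ``fixation_freq`` within the cluster and the two consensuses
    differ; it is radical when the consensuses fall in different property
    classes. theta_II is the excess of radical fixed differences over the
    rate expected if fixed differences drew their radical/conservative
    status from the within-cluster baseline; the SE comes from a
    delta-method combination of the binomial variances.
    """
    rows_a = [alignment[g] for g in cluster_a]
    rows_b = [alignment[g] for g in cluster_b]
    L = len(rows_a[0])
    kept, fixed_radical, fixed_any = [], [], []
    n_within = 0
    n_within_radical = 0
    for c in range(L):
        col_a = [r[c] for r in rows_a]
        col_b = [r[c] for r in rows_b]
        gap_frac = sum(x in "-." for x in col_a + col_b) / (len(col_a) + len(col_b))
        if gap_frac > max_gap_frac:
            continue
        kept.append(c + 1)
        cons_a, freq_a = _consensus(col_a)
        cons_b, freq_b = _consensus(col_b)
        # within-cluster changes feed the radical/conservative baseline
        for col, cons in ((col_a, cons_a), (col_b, cons_b)):
            minor = {x for x in col if x not in "-." and x != cons}
            for m in minor:
                n_within += 1
                n_within_radical += is_radical(cons, m)
        fixed = (
            cons_a != "-" and cons_b != "-" and cons_a != cons_b
            and freq_a >= fixation_freq and freq_b >= fixation_freq
        )
        fixed_any.append(fixed)
        fixed_radical.append(fixed and is_radical(cons_a, cons_b))
    N = len(kept)
    if N == 0:
        raise ValueError("no usable columns")
    d = sum(fixed_any)
    r = sum(fixed_radical)
    # baseline radical fraction, lightly smoothed toward the random-pair rate
    pi = (n_within_radical + _P_RADICAL0) / (n_within + 1.0)
    note = ""
    if d == 0:
        warnings.warn("no between-cluster fixed differences; theta_II set to 0")
        note = "no fixed differences"
        theta, se = 0.0, 0.0
        qk = np.zeros(N)
    else:
        # model: type-II sites (prob theta) always show a radical fixed
        # difference; neutral sites fix with prob phi, radical w.p. pi given
        # fixed. Moments: D = theta + (1-theta)phi, R = theta + (1-theta)phi*pi
        # => theta = (R - D*pi)/(1 - pi)
        R = r / N
        D = d / N
        theta = (R - D * pi) / (1.0 - pi)
        phi = (D - theta) / (1.0 - theta) if theta < 1 else 0.0
        var_R = R * (1 - R) / N
        var_D = D * (1 - D) / N
        cov_RD = R * (1 - D) / N  # radical-fixed sites are a subset of fixed sites
        var_pi = pi * (1 - pi) / max(n_within, 1)
        a = 1.0 / (1.0 - pi)
        b = -pi / (1.0 - pi)
        c = (R - D) / (1.0 - pi) ** 2
        se = float(np.sqrt(max(
            a * a * var_R + b * b * var_D + 2 * a * b * cov_RD + c * c * var_pi, 0.0
        )))
        neutral_radical = max((1.0 - theta) * phi * pi, 0.0)
        post = theta / (theta + neutral_radical) if theta > 0 else 0.0
        qk = np.array([post if rad else 0.0 for rad in fixed_radical])
    result = DivergenceResult(
        div_type="II",
        theta=float(theta),
        se=se,
        lrt=None,
        p_value=None,
        qk=qk,
        columns=kept,
        note=note,
    )
    result.critical_sites = result.critical(qk_threshold)
    return result


# ---------------------------------------------------------------------------


def divergence_report(
    alignment: dict[str, str],
    subfamily_map: dict[str, str],
    min_cluster: int = 4,
    qk_threshold: float = 0.9,
) -> tuple[list[dict], dict[tuple[str, str, str], DivergenceResult]]:
    """Type-I and type-II results for every eligible subfamily pair.

    Subfamilies with fewer than ``min_cluster`` members are skipped with a
    recorded reason. Returns (report rows, {(sf_a, sf_b, type): result}).
    """
    clusters: dict[str, list[str]] = {}
    for gene, sf in subfamily_map.items():
        if gene in alignment:
            clusters.setdefault(sf, []).append(gene)
    for sf in clusters:
        clusters[sf].sort()
    names = sorted(clusters)
    rows: list[dict] = []
    results: dict[tuple[str, str, str], DivergenceResult] = {}
    for i, sa in enumerate(names):
        for sb in names[i + 1 :]:
            pair_name = f"{sa} vs {sb}"
            small = [s for s in (sa, sb) if len(clusters[s]) < min_cluster]
            if small:
                rows.append({
                    "pair": pair_name, "type": "skipped", "theta": "NA", "se": "NA",
                    "lrt": "NA", "p": "NA", "n_critical": "NA",
                    "note": f"cluster(s) {','.join(small)} below {min_cluster} sequences",
                })
                continue
            x1, x2, cols = site_substitution_counts(alignment, clusters[sa], clusters[sb])
            r1 = estimate_theta1(x1, x2, columns=cols, qk_threshold=qk_threshold)
            r2 = estimate_theta2(
                alignment, clusters[sa], clusters[sb], qk_threshold=qk_threshold
            )
            for r, tname in ((r1, "I"), (r2, "II")):
                results[(sa, sb, tname)] = r
                rows.append({
                    "pair": pair_name, "type": tname,
                    "theta": round(r.theta, 6), "se": round(r.se, 6) if np.isfinite(r.se) else "NA",
                    "lrt": round(r.lrt, 6) if r.lrt is not None else "NA",
                    "p": round(r.p_value, 6) if r.p_value is not None else "NA",
                    "n_critical": len(r.critical_sites),
                    "note": r.note + (" boundary" if r.boundary else ""),
                })
    return rows, results
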