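"""Differential expression and position-expression concordance.

Expression changes are called from log2-intensity replicate matrices with
an empirical-Bayes moderated t-statistic: per-gene variances are shrunk
toward a common prior (prior df d0 and prior variance s0^2 fitted by
moment matching of the log residual variances to a scaled-F model), p
values are Benjamini-Hochberg adjusted, and a gene is up/down when
|log2FC| > 0.5 at FDR < 0.05.

Genes are classified by their peripheral behaviour between conditions —
II (stays internal), PP (stays peripheral), IP (moves toward the
periphery), PI (moves away), AMB (conflicting or undetermined) — and the
expected-direction concordance (IP with down, PI with up) is tested by
Fisher's exact test on the {IP,PI}x{up,down} table of genes that both
moved and changed expression. Reference differentiation programs (e.g.
iPS -> hepatocyte fold changes) are compared by two-sample KS tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .intervals import overlaps_any

logger = logging.getLogger(__name__)


# ------------------------------------------------------- moderated statistics

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def fit_f_dist(variances: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-matching fit of a scaled-F prior to per-gene sample variances.

    Returns (prior_df d0, prior_variance s0sq). Follows the classic
    log-variance moment equations: if s^2 ~ s0^2 F(df, d0), then
    log s^2 - digamma(df/2) + log(df/2) has mean log s0^2 + digamma(d0/2)
    - log(d0/2) and variance trigamma(df/2) + trigamma(d0/2).
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) < 2:
        return np.inf, float(np.mean(v)) if len(v) else 1.0
    z = np.log(v)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    return d0, s0sq


def moderated_t(expr_a: np.ndarray, expr_b: np.ndarray) -> pd.DataFrame:
    """Two-group empirical-Bayes moderated t per gene (rows = genes).

    expr_a is the test (NET) group, expr_b the control; log2FC = mean_a -
    mean_b. Returns log2fc, t, p_value, df_total, posterior variance.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 replicates per group")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    lfc = mean_a - mean_b
    df_resid = n1 + n2 - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    d0, s0sq = fit_f_dist(s2, df_resid)
    if np.isfinite(d0):
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    else:
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    return pd.DataFrame({"log2fc": lfc, "t": t, "p_value": p,
                         "df_total": df_total, "s2_post": s2_post})


def call_de(expr_net: pd.DataFrame, expr_control: pd.DataFrame,
            fdr: float = 0.05, lfc: float = 0.5) -> pd.DataFrame:
    """DE call per gene: 'up' / 'down' / 'nc' at |log2FC| > lfc and BH-adjusted
    p < fdr. Matrices are genes x replicates with matching gene indexes."""
    genes = expr_net.index
    if not genes.equals(expr_control.index):
        expr_control = expr_control.loc[genes]
    res = moderated_t(expr_net.to_numpy(), expr_control.to_numpy())
    res.index = genes
    res["adj_p"] = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
    call = np.full(len(res), "nc", dtype=object)
    sig = res["adj_p"].to_numpy() < fdr
    call[sig & (res["log2fc"].to_numpy() > lfc)] = "up"
    call[sig & (res["log2fc"].to_numpy() < -lfc)] = "down"
    res["de_call"] = call
    return res


# ------------------------------------------------------- positional classes

POSITION_CLASSES = ("II", "PP", "PI", "IP", "AMB")


def classify_position(genes: pd.DataFrame, lads_control: pd.DataFrame,
                      lads_net: pd.DataFrame, drs: pd.DataFrame) -> pd.Series:
    """One of II/PP/PI/IP/AMB per gene.

    DR overlap wins: IP-DR -> IP, PI-DR -> PI, both -> AMB. Without a DR:
    in LADs of both conditions -> PP, in neither -> II, in exactly one
    (position changed but no called DR) -> AMB.
    """
    ip = drs[drs["dr_class"] == "IP"] if len(drs) else drs
    pi = drs[drs["dr_class"] == "PI"] if len(drs) else drs
    in_ip = overlaps_any(genes, ip) if len(ip) else np.zeros(len(genes), dtype=bool)
    in_pi = overlaps_any(genes, pi) if len(pi) else np.zeros(len(genes), dtype=bool)
    in_ctrl = overlaps_any(genes, lads_control) if len(lads_control) else np.zeros(len(genes), dtype=bool)
    in_net = overlaps_any(genes, lads_net) if len(lads_net) else np.zeros(len(genes), dtype=bool)
    cls = np.full(len(genes), "AMB", dtype=object)
    no_dr = ~in_ip & ~in_pi
    cls[in_ip & ~in_pi] = "IP"
    cls[in_pi & ~in_ip] = "PI"
    cls[no_dr & in_ctrl & in_net] = "PP"
    cls[no_dr & ~in_ctrl & ~in_net] = "II"
    return pd.Series(cls, index=genes.index, name="position_class")


def gene_window_delta(genes: pd.DataFrame, track_control, track_net,
                      window: int = 100_000) -> pd.Series:
    """Mean NET minus control signal over a `window` centered on each gene.

    The window is centered on the gene midpoint (strand-agnostic) and
    truncated at chromosome ends; fragments enter by midpoint. Genes with
    no informative fragment in the window get NaN (logged).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    fmap = track_control.fragment_map
    out = np.full(len(genes), np.nan)
    n_empty = 0
    for pos, (chrom, s, e) in enumerate(zip(genes["chrom"], genes["start"], genes["end"])):
        if chrom not in fmap.chrom_lengths:
            n_empty += 1
            continue
        mid = (s + e) / 2.0
        lo = max(mid - window / 2.0, 0)
        hi = min(mid + window / 2.0, fmap.chrom_lengths[chrom])
        sl = fmap.interval_to_fragments(chrom, lo, hi)
        vc = track_control.values[sl]
        vn = track_net.values[sl]
        mc = vc[~np.isnan(vc)]
        mn = vn[~np.isnan(vn)]
        if len(mc) == 0 or len(mn) == 0:
            n_empty += 1
            continue
        out[pos] = mn.mean() - mc.mean()
    if n_empty:
        logger.info("gene_window_delta: %d genes with no informative fragments in window", n_empty)
    return pd.Series(out, index=genes.index, name="damid_delta")


# ------------------------------------------------------- concordance and KS

@dataclass
class ConcordanceResult:
    table: np.ndarray  # rows IP, PI; cols up, down
    expected_direction_fraction: float
    odds_ratio: float
    fisher_p: float
    n_genes: int
    ecdfs: dict = field(default_factory=dict)


def concordance(genes: pd.DataFrame) -> ConcordanceResult:
    """Position-expression direction agreement over moved AND DE genes.

    Expected direction: IP (toward periphery) with down, PI (released)
    with up. `genes` must carry position_class, de_call and (optionally)
    damid_delta columns; ecdfs of |damid_delta| are returned per
    class-direction group (the dark/pale populations).
    """
    moved = genes["position_class"].isin(["IP", "PI"])
    de = genes["de_call"].isin(["up", "down"])
    sub = genes[moved & de]
    tab = np.array([
        [int(((sub["position_class"] == "IP") & (sub["de_call"] == "up")).sum()),
         int(((sub["position_class"] == "IP") & (sub["de_call"] == "down")).sum())],
        [int(((sub["position_class"] == "PI") & (sub["de_call"] == "up")).sum()),
         int(((sub["position_class"] == "PI") & (sub["de_call"] == "down")).sum())],
    ])
    n = int(tab.sum())
    if n == 0:
        warnings.warn("concordance: no genes both repositioned and differentially expressed")
        return ConcordanceResult(tab, float("nan"), float("nan"), float("nan"), 0)
    expected = tab[0, 1] + tab[1, 0]  # IP&down + PI&up
    frac = expected / n
    odds, p = stats.fisher_exact(tab, alternative="two-sided")
    ecdfs = {}
    if "damid_delta" in genes.columns:
        for pcls in ("IP", "PI"):
            for dcall in ("up", "down"):
                grp = genes[(genes["position_class"] == pcls) & (genes["de_call"] == dcall)]
                v = np.abs(grp["damid_delta"].to_numpy())
                v = np.sort(v[~np.isnan(v)])
                ecdfs[f"{pcls}_{dcall}"] = (v, np.arange(1, len(v) + 1) / len(v) if len(v) else np.array([]))
    return ConcordanceResult(tab, float(frac), float(odds), float(p), n, ecdfs)


@dataclass
class ReferenceOverlapResult:
    ks_up: tuple[float, float] | None  # (D, p) NET-up vs background
    ks_down: tuple[float, float] | None
    n_ref_up_threshold: int  # reference genes above the fold-change cutoff
    net_up_in_ref_up: int
    net_down_in_ref_up: int
    genes_above_threshold: list = field(default_factory=list)


def reference_overlap(genes: pd.DataFrame, reference: pd.Series,
                      threshold_fold: float = 2.0) -> ReferenceOverlapResult:
    """Compare NET-regulated genes against a reference differentiation program.

    `reference` maps gene ID -> reference log2FC (e.g. iPS->hepatocyte).
    Two-sample KS tests compare the reference fold changes of NET-up (and
    NET-down) genes against all assayed genes present in the reference;
    genes above the reference 2-fold upregulation threshold are flagged and
    the numbers of NET-up/-down genes within that set reported.
    """
    common = genes.index.intersection(reference.index)
    ref = reference.loc[common].astype(float)
    calls = genes.loc[common, "de_call"]
    background = ref.to_numpy()
    results = {}
    for direction in ("up", "down"):
        vals = ref[calls == direction].to_numpy()
        if len(vals) < 3 or len(background) < 3:
            warnings.warn(f"reference_overlap: <3 overlapping NET-{direction} genes; KS skipped")
            results[direction] = None
        else:
            d, p = stats.ks_2samp(vals, background, alternative="two-sided", method="auto")
            results[direction] = (float(d), float(p))
    log2_thr = np.log2(threshold_fold)
    above = ref[ref > log2_thr]
    net_up = int((calls.loc[above.index] == "up").sum())
    net_down = int((calls.loc[above.index] == "down").sum())
    return ReferenceOverlapResult(
        ks_up=results["up"], ks_down=results["down"],
        n_ref_up_threshold=len(above),
        net_up_in_ref_up=net_up, net_down_in_ref_up=net_down,
        genes_above_threshold=list(above.index),
    )


@dataclass
class CrossSystemOverlap:
    n_intersection: int
    n_a_only: int
    n_b_only: int
    fraction_a_in_b: float
    hypergeom_p: float


def cross_system_overlap(set_a: set, set_b: set, universe: set) -> CrossSystemOverlap:
    """Overlap of two gene sets within a universe, with hypergeometric
    enrichment p (P[X >= observed intersection])."""
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & set(universe)
    b = set(set_b) & set(universe)
    inter = a & b
    n, K, nn, k = len(universe), len(a), len(b), len(inter)
    p = float(stats.hypergeom.sf(k - 1, n, K, nn))
    return CrossSystemOverlap(
        n_intersection=k, n_a_only=len(a - b), n_b_only=len(b - a),
        fraction_a_in_b=k / len(a) if a else float("nan"),
        hypergeom_p=p,
    )
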