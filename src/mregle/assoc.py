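"""Association stage: orthogonalized embeddings, per-coordinate GWAS, the
summed chi-squared combined statistic, clumping and locus construction.

The embeddings from the representation model are first projected onto their
principal components so the coordinates are exactly sample-uncorrelated;
each coordinate is then tested against every variant by covariate-adjusted
ordinary least squares, and the per-coordinate Wald chi-squared statistics
are summed per variant.  Because the coordinates are uncorrelated, the sum
is referred to a chi-squared distribution with m (the number of retained
coordinates) degrees of freedom — asymptotically the same test as a MANOVA
of the multivariate embedding on the variant, which this module also
implements as an independent oracle.

Genome-wide significant hits are greedy clump leads (p < 5e-8, mutually
independent at r-squared < 0.1 in a reference panel); loci are the LD spans
of the hits (r-squared >= 0.1), merged when separated by fewer than 250 kb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import EmbeddingMatrix
from .synthgen import GenotypeMatrix

__all__ = [
    "PCEmbedding",
    "AssocTable",
    "CombinedResult",
    "Hit",
    "Locus",
    "orthogonalize",
    "variant_qc",
    "assoc_scan",
    "assoc_scan_all",
    "combine_chi2",
    "manova_oracle",
    "clump",
    "build_loci",
    "expected_chi2",
    "overlap_known",
    "genomic_inflation",
    "read_bed_intervals",
    "write_loci_bed",
]

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class PCEmbedding:
    """Exactly sample-uncorrelated embedding coordinates (PC scores)."""

    sample_ids: list[str]
    values: np.ndarray  # (n, m)
    rotation: np.ndarray  # (d, m)
    dropped_components: list[int] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.values.shape[1]


def orthogonalize(embeddings: EmbeddingMatrix, tol: float = 1e-12) -> PCEmbedding:
    """Full-retention PCA of the raw embeddings.

    All components with non-zero variance are kept (no information loss);
    zero-variance components are dropped with a loud warning because the
    retained count m becomes the degrees of freedom of the combined test.
    Component signs follow the largest-|loading| convention.
    """
    X = embeddings.values
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more samples than embedding dims (n={n}, d={d})")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = S > tol * max(S.max(), 1.0)
    dropped = [int(i) for i in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance component(s) {dropped}; "
            f"combined-test df reduced to {int(keep.sum())}", stacklevel=2)
    Vt = Vt[keep]
    S = S[keep]
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    scores = Xc @ (Vt * flip[:, None]).T
    return PCEmbedding(list(embeddings.sample_ids), scores, (Vt * flip[:, None]).T, dropped)


# ---------------------------------------------------------------------------
# variant QC


def variant_qc(variants: pd.DataFrame, maf_min: float = 0.001, info_min: float = 0.8,
               miss_max: float = 0.05, hwe_min: float = 1.0e-10) -> pd.DataFrame:
    """Variant filters exactly as printed: maf >= 0.001, INFO >= 0.8,
    missing fraction <= 0.05, HWE p > 1e-10.  A missing column skips that
    filter with a warning."""
    mask = np.ones(len(variants), dtype=bool)
    checks = [("maf", lambda c: c >= maf_min), ("info", lambda c: c >= info_min),
              ("missing_frac", lambda c: c <= miss_max), ("hwe_p", lambda c: c > hwe_min)]
    for col, fn in checks:
        if col not in variants.columns:
            warnings.warn(f"variant table lacks {col!r}; that filter is skipped", stacklevel=2)
            continue
        mask &= fn(variants[col].to_numpy(dtype=float))
    return variants.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# association scans


def _covariate_design(n: int, covariates: pd.DataFrame | np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) \
        else np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _residualize(M: np.ndarray, design: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(design)
    return M - Q @ (Q.T @ M)


def _check_collinear(design: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"collinear covariate design (columns: {list(names)})")


def assoc_scan_all(pc_values: np.ndarray, genotypes: GenotypeMatrix,
                   covariates: pd.DataFrame | np.ndarray | None = None) -> "AssocTable":
    """Covariate-adjusted OLS of every coordinate on every variant.

    Uses Frisch-Waugh residualization: both the phenotypes and the dosages
    are residualized against the covariate design (with intercept) once,
    after which each (variant, coordinate) cell is a simple regression.
    Wald chi2 = (beta / se)^2 with a chi-squared(1) p-value.  Monomorphic
    variants get NA rows.
    """
    Y = np.atleast_2d(np.asarray(pc_values, dtype=float))
    if Y.shape[0] == 1 and genotypes.n != 1:
        Y = Y.T
    n, m = Y.shape
    if genotypes.n != n:
        raise ValueError("phenotype and genotype sample counts disagree")
    design = _covariate_design(n, covariates)
    names = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
             else [f"c{i}" for i in range(design.shape[1] - 1)])
    _check_collinear(design, ["intercept"] + names)

    G = genotypes.dosages.copy()
    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    Yr = _residualize(Y, design)
    Gr = _residualize(G, design)
    q = design.shape[1]
    dof = n - q - 1
    if dof <= 0:
        raise ValueError("not enough samples for the covariate-adjusted scan")

    gg = np.einsum("ij,ij->j", Gr, Gr)  # (p,)
    mono = gg <= 1e-12 * n
    gg_safe = np.where(mono, 1.0, gg)
    gy = Gr.T @ Yr  # (p, m)
    yy = np.einsum("ij,ij->j", Yr, Yr)  # (m,)
    beta = gy / gg_safe[:, None]
    rss = np.maximum(yy[None, :] - beta**2 * gg_safe[:, None], 0.0)
    sigma2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / gg_safe[:, None])
        chi2 = np.where(se > 0, (beta / se) ** 2, np.inf)
    pvals = np.maximum(stats.chi2.sf(chi2, df=1), _P_FLOOR)
    beta[mono] = np.nan
    se[mono] = np.nan
    chi2[mono] = np.nan
    pvals[mono] = np.nan
    return AssocTable(
        variants=genotypes.variants[["id", "chrom", "pos"]].copy(),
        beta=beta, se=se, chi2=chi2, p=pvals, n=n,
        covariate_names=names, provenance={"engine": "ols-wald", "dof": dof},
    )


def assoc_scan(pc_column: np.ndarray, genotype_column: np.ndarray,
               covariates: pd.DataFrame | np.ndarray | None = None) -> dict:
    """Single-coordinate, single-variant association (convenience wrapper).

    Raises on a constant dosage column (flagged monomorphic by the batch
    scan) and on collinear covariates.
    """
    g = np.asarray(genotype_column, dtype=float)
    if np.nanstd(g) == 0:
        raise ValueError("constant (monomorphic) dosage column")
    gm = GenotypeMatrix(["_"] * g.size, g[:, None],
                        pd.DataFrame({"id": ["v"], "chrom": ["0"], "pos": [1],
                                      "ref": "A", "alt": "G", "maf": 0.5, "info": 1.0,
                                      "missing_frac": 0.0, "hwe_p": 1.0}))
    tab = assoc_scan_all(np.asarray(pc_column, dtype=float)[:, None], gm, covariates)
    return {"beta": float(tab.beta[0, 0]), "se": float(tab.se[0, 0]),
            "chi2": float(tab.chi2[0, 0]), "p": float(tab.p[0, 0])}


@dataclass
class AssocTable:
    """Per-variant, per-coordinate association results."""

    variants: pd.DataFrame  # id, chrom, pos
    beta: np.ndarray  # (p, m)
    se: np.ndarray
    chi2: np.ndarray
    p: np.ndarray
    n: int
    covariate_names: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.chi2.shape[1]


@dataclass
class CombinedResult:
    """Summed chi-squared per variant with its chi-squared(m) p-value."""

    table: pd.DataFrame  # id, chrom, pos, sum_chi2, df, p, log10p
    df: int


def combine_chi2(assoc: AssocTable) -> CombinedResult:
    """Sum the per-coordinate chi-squared statistics for each variant and
    refer the sum to chi-squared(m).

    The survival probability is computed in log space and floored at the
    smallest positive normal double so extreme signals keep a usable
    log10 p.
    """
    m = assoc.m
    sum_chi2 = np.nansum(assoc.chi2, axis=1)
    all_na = np.all(np.isnan(assoc.chi2), axis=1)
    logsf = stats.chi2.logsf(sum_chi2, df=m)
    p = np.maximum(np.exp(logsf), _P_FLOOR)
    log10p = logsf / np.log(10.0)
    tab = assoc.variants.copy()
    tab["sum_chi2"] = np.where(all_na, np.nan, sum_chi2)
    tab["df"] = m
    tab["p"] = np.where(all_na, np.nan, p)
    tab["log10p"] = np.where(all_na, np.nan, log10p)
    return CombinedResult(tab, m)


def combine_pc(pc: PCEmbedding, genotypes: GenotypeMatrix,
               covariates: pd.DataFrame | np.ndarray | None = None) -> CombinedResult:
    """Scan every PC coordinate and combine, in one call."""
    return combine_chi2(assoc_scan_all(pc.values, genotypes, covariates))


def manova_oracle(Y: np.ndarray, genotype_column: np.ndarray,
                  covariates: pd.DataFrame | np.ndarray | None = None) -> float:
    """Wilks' likelihood-ratio test of one variant on an m-variate outcome.

    Covariates (plus intercept) are projected out of both sides.  For a
    rank-one hypothesis the Wilks lambda is algebraically
    Lambda = 1 / (1 + T2 / v_e) with T2 the Hotelling statistic and v_e the
    error degrees of freedom; T2 = v_e (1 - Lambda) / Lambda is referred to
    its chi-squared(m) asymptotic reference, which reduces *exactly* to the
    univariate Wald chi-squared when m = 1.  Used as an
    asymptotic-equivalence oracle for the summed chi-squared statistic.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    n, m = Y.shape
    g = np.asarray(genotype_column, dtype=float)
    if g.std() == 0:
        raise ValueError("constant (monomorphic) dosage column")
    design = _covariate_design(n, covariates)
    _check_collinear(design, range(design.shape[1]))
    Yr = _residualize(Y, design)
    gr = _residualize(g[:, None], design).ravel()
    gg = gr @ gr
    b = Yr.T @ gr / gg  # (m,)
    T = Yr.T @ Yr
    H = np.outer(b, b) * gg
    E = T - H
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_e <= 0 or sign_t <= 0:
        raise ValueError("singular error matrix in MANOVA (m too large for n?)")
    wilks_lambda = np.exp(logdet_e - logdet_t)
    v_e = n - design.shape[1] - 1
    stat = v_e * (1.0 - wilks_lambda) / wilks_lambda
    return float(max(stats.chi2.sf(stat, df=m), _P_FLOOR))


def genomic_inflation(combined: CombinedResult) -> float:
    """Median summed chi-squared over the chi-squared(df) median (lambda_GC)."""
    obs = np.nanmedian(combined.table["sum_chi2"].to_numpy())
    return float(obs / stats.chi2.ppf(0.5, df=combined.df))


# ---------------------------------------------------------------------------
# hits and loci


@dataclass
class Hit:
    """A clump: a lead variant plus the variants assigned to it."""

    variant_id: str
    chrom: str
    pos: int
    p: float
    sum_chi2: float
    members: list[tuple[str, float]]  # (variant id, r2 with the lead)


@dataclass
class Locus:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    hit_ids: list[str]
    known: bool | None = None


def _panel_r2(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared Pearson correlation of mean-imputed panel dosages."""
    G = gm.dosages.copy()
    nan_mask = np.isnan(G)
    if nan_mask.any():
        col_mean = np.nanmean(G, axis=0)
        G[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = G.std(axis=0)
    sd[sd == 0] = np.nan
    Z = (G - G.mean(axis=0)) / sd
    r = Z.T @ Z / G.shape[0]
    return r**2


def clump(combined: CombinedResult, ref_genotypes: GenotypeMatrix,
          p_thresh: float = 5.0e-8, r2_thresh: float = 0.1,
          radius_kb: float = 500.0) -> list[Hit]:
    """Greedy LD clumping of the combined summary statistics.

    Repeatedly takes the most significant unassigned variant with
    p < ``p_thresh`` as a lead, and assigns to its clump every unassigned
    variant (at any p) on the same chromosome within ``radius_kb`` whose
    panel r-squared with the lead is >= ``r2_thresh``.  The leads are the
    hits, mutually independent at r-squared < ``r2_thresh``.  Variants
    absent from the panel are excluded with a warning.
    """
    tab = combined.table
    panel_ids = {vid: j for j, vid in enumerate(ref_genotypes.variants["id"])}
    missing = [v for v in tab["id"] if v not in panel_ids]
    if missing:
        warnings.warn(f"{len(missing)} variant(s) absent from the reference panel "
                      "were excluded from clumping", stacklevel=2)
    tab = tab[tab["id"].isin(panel_ids)].reset_index(drop=True)
    r2 = _panel_r2(ref_genotypes)
    radius_bp = radius_kb * 1000.0

    order = tab.sort_values(["p", "pos"], kind="mergesort").index
    assigned = np.zeros(len(tab), dtype=bool)
    hits: list[Hit] = []
    pos = tab["pos"].to_numpy()
    chrom = tab["chrom"].astype(str).to_numpy()
    pvals = tab["p"].to_numpy()
    for i in order:
        if assigned[i] or not (pvals[i] < p_thresh) or np.isnan(pvals[i]):
            continue
        assigned[i] = True
        ji = panel_ids[tab.at[i, "id"]]
        members = [(tab.at[i, "id"], 1.0)]
        for k in np.flatnonzero(~assigned):
            if chrom[k] != chrom[i] or abs(pos[k] - pos[i]) > radius_bp:
                continue
            rr = r2[ji, panel_ids[tab.at[k, "id"]]]
            if np.isfinite(rr) and rr >= r2_thresh:
                assigned[k] = True
                members.append((tab.at[k, "id"], float(rr)))
        hits.append(Hit(tab.at[i, "id"], chrom[i], int(pos[i]), float(pvals[i]),
                        float(tab.at[i, "sum_chi2"]), members))
    return hits


def build_loci(hits: list[Hit], ref_genotypes: GenotypeMatrix, r2_span: float = 0.1,
               merge_gap_bp: int = 250_000, radius_kb: float = 500.0) -> list[Locus]:
    """LD spans of the hits, merged when separated by fewer than 250 kb.

    Each hit's interval covers every reference-panel variant on the same
    chromosome within ``radius_kb`` whose r-squared with the hit is
    >= ``r2_span`` (the hit itself included).  Same-chromosome intervals
    with gap < ``merge_gap_bp`` are merged transitively; a gap of exactly
    ``merge_gap_bp`` stays unmerged.
    """
    if not hits:
        return []
    panel = ref_genotypes.variants
    panel_ids = {vid: j for j, vid in enumerate(panel["id"])}
    r2 = _panel_r2(ref_genotypes)
    ppos = panel["pos"].to_numpy()
    pchrom = panel["chrom"].astype(str).to_numpy()
    radius_bp = radius_kb * 1000.0

    intervals = []
    for h in hits:
        j = panel_ids.get(h.variant_id)
        if j is None:
            intervals.append((h.chrom, h.pos, h.pos, h.variant_id))
            continue
        near = (pchrom == str(h.chrom)) & (np.abs(ppos - h.pos) <= radius_bp)
        ld = near & (np.nan_to_num(r2[j], nan=0.0) >= r2_span)
        span_pos = ppos[ld] if ld.any() else np.array([h.pos])
        intervals.append((str(h.chrom), int(span_pos.min()), int(span_pos.max()),
                          h.variant_id))

    loci: list[Locus] = []
    by_chrom: dict[str, list] = {}
    for chrom, s, e, hid in intervals:
        by_chrom.setdefault(chrom, []).append((s, e, hid))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        cur_s, cur_e, cur_hits = ivs[0][0], ivs[0][1], [ivs[0][2]]
        for s, e, hid in ivs[1:]:
            if s - cur_e < merge_gap_bp:
                cur_e = max(cur_e, e)
                cur_hits.append(hid)
            else:
                loci.append(Locus(chrom, cur_s, cur_e, cur_hits))
                cur_s, cur_e, cur_hits = s, e, [hid]
        loci.append(Locus(chrom, cur_s, cur_e, cur_hits))
    return loci


def expected_chi2(combined: CombinedResult, known_variants) -> tuple[float, float]:
    """Mean and standard error of the summed chi-squared over the variants
    also present in ``known_variants`` (the rediscovered hits)."""
    known = set(known_variants)
    vals = combined.table.loc[combined.table["id"].isin(known), "sum_chi2"].dropna()
    if len(vals) == 0:
        warnings.warn("no overlap with the known-variant list", stacklevel=2)
        return (float("nan"), float("nan"))
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return mean, se


def overlap_known(loci: list[Locus], known: pd.DataFrame) -> tuple[list[Locus], dict]:
    """Flag each locus as known iff it overlaps any known interval by >= 1 bp.

    ``known`` needs columns chrom, start, end with 1-based inclusive
    coordinates (use :func:`read_bed_intervals` for BED input).
    """
    for col in ("chrom", "start", "end"):
        if col not in known.columns:
            raise ValueError(f"known-intervals table lacks column {col!r}")
    for i, row in known.iterrows():
        if row["end"] < row["start"]:
            raise ValueError(f"malformed known interval at line {i + 1}: end < start")
    for loc in loci:
        sub = known[known["chrom"].astype(str) == str(loc.chrom)]
        loc.known = bool(((sub["start"] <= loc.end) & (sub["end"] >= loc.start)).any())
    n_known = sum(bool(l.known) for l in loci)
    return loci, {"known": n_known, "novel": len(loci) - n_known}


def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str})
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def write_loci_bed(loci: list[Locus], path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{','.join(loc.hit_ids)}\n")
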