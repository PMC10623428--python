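"""MALDI imaging-MS average-spectrum screening.

The unit of analysis is a per-sample average peak list: per-pixel
spectra are assumed to have been TIC-normalized and averaged upstream
(an average over ~500 pixels per tissue section).  This module aligns
peak lists across samples into a signal matrix, applies the
strong-signal rule (keep m/z bins whose summed intensity exceeds 5% of
the largest summed intensity), screens bins for group differences with
a Kruskal-Wallis + Dunn-Bonferroni cascade under Benjamini-Hochberg
FDR, summarises the matrix by PCA and Ward clustering, and annotates
m/z values against a bundled formula table via monoisotopic adduct
masses at +/-10 ppm.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .constants import ADDUCT_MASSES, MONOISOTOPIC_MASSES
from . import inference

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSpectrum",
    "SignalMatrix",
    "AnnotationHit",
    "tic_normalize",
    "align_mz",
    "collapse_technical_replicates",
    "select_strong_signals",
    "screen_significance",
    "pca_summary",
    "ward_heatmap",
    "monoisotopic_mass",
    "annotate_mass",
    "load_bundled_annotation_table",
]

DEFAULT_TOLERANCE_PPM = 10.0
STRONG_SIGNAL_FRACTION = 0.05


@dataclass(frozen=True)
class PeakSpectrum:
    """A per-sample average peak list (m/z ascending, intensities >= 0)."""

    sample_id: str
    group: str
    mz: np.ndarray
    intensity: np.ndarray
    bio_replicate: str = "b1"
    tech_replicate: str = "t1"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", it)
        if mz.shape != it.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-d arrays")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class SignalMatrix:
    """Samples x aligned m/z bins of TIC-normalized intensities."""

    mz_bins: np.ndarray
    intensities: pd.DataFrame  # index = sample_id, columns = bin index
    sample_meta: pd.DataFrame  # index = sample_id; columns group, bio/tech replicate

    @property
    def sum_intensity(self) -> np.ndarray:
        """Per-bin summed intensity across all samples (sum I_m/z)."""
        return self.intensities.to_numpy().sum(axis=0)

    def restrict(self, bin_idx) -> "SignalMatrix":
        cols = self.intensities.columns[np.asarray(bin_idx)]
        return SignalMatrix(self.mz_bins[np.asarray(bin_idx)],
                            self.intensities[cols], self.sample_meta)


@dataclass(frozen=True)
class AnnotationHit:
    query_mz: float
    name: str
    formula: str
    adduct: str
    theoretical_mz: float
    ppm_error: float


def tic_normalize(spectrum: PeakSpectrum) -> PeakSpectrum:
    """Divide intensities by their total ion current; output sums to 1."""
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise ValueError(f"spectrum {spectrum.sample_id!r} has zero total intensity")
    return PeakSpectrum(spectrum.sample_id, spectrum.group,
                        spectrum.mz, spectrum.intensity / total,
                        spectrum.bio_replicate, spectrum.tech_replicate)


def align_mz(spectra, tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
             normalize: bool = True) -> SignalMatrix:
    """Align peak lists across samples into common m/z bins.

    Pooled m/z values are clustered by single linkage: a sorted run of
    peaks belongs to one bin while consecutive gaps stay within the ppm
    tolerance.  Bin centers are intensity-weighted means.  When one
    sample contributes several peaks to a bin, the most intense one is
    kept and the collision is logged.
    """
    spectra = list(spectra)
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if not spectra:
        raise ValueError("no spectra supplied")
    if normalize:
        spectra = [tic_normalize(s) for s in spectra]

    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")

    mz_all, it_all, samp_all = [], [], []
    for si, s in enumerate(spectra):
        mz_all.append(s.mz)
        it_all.append(s.intensity)
        samp_all.append(np.full(s.mz.size, si))
    mz = np.concatenate(mz_all)
    it = np.concatenate(it_all)
    samp = np.concatenate(samp_all)
    order = np.argsort(mz, kind="stable")
    mz, it, samp = mz[order], it[order], samp[order]

    # single-linkage chaining: break where the relative gap exceeds tol
    gaps = np.diff(mz) / mz[:-1] > tolerance_ppm * 1e-6
    bin_id = np.concatenate([[0], np.cumsum(gaps)])
    n_bins = int(bin_id[-1]) + 1

    centers = np.zeros(n_bins)
    mat = np.zeros((len(spectra), n_bins))
    collisions = 0
    for b in range(n_bins):
        mask = bin_id == b
        w = it[mask]
        centers[b] = float(np.average(mz[mask], weights=w)) if w.sum() > 0 else float(mz[mask].mean())
        for si, inten in zip(samp[mask], w):
            if mat[si, b] > 0:
                collisions += 1
                mat[si, b] = max(mat[si, b], inten)
            else:
                mat[si, b] = inten
    if collisions:
        logger.info("align_mz: %d peak collisions resolved by max intensity", collisions)

    meta = pd.DataFrame({
        "group": [s.group for s in spectra],
        "bio_replicate": [s.bio_replicate for s in spectra],
        "tech_replicate": [s.tech_replicate for s in spectra],
    }, index=pd.Index(ids, name="sample_id"))
    df = pd.DataFrame(mat, index=meta.index, columns=range(n_bins))
    return SignalMatrix(centers, df, meta)


def collapse_technical_replicates(matrix: SignalMatrix) -> SignalMatrix:
    """Average technical replicates within each (group, biological replicate).

    Treating technical replicates as independent samples inflates n;
    this collapse yields one row per biological replicate.
    """
    key = matrix.sample_meta["group"].astype(str) + "|" + matrix.sample_meta["bio_replicate"].astype(str)
    collapsed = matrix.intensities.groupby(key).mean()
    meta = matrix.sample_meta.groupby(key).first()[["group", "bio_replicate"]]
    meta["tech_replicate"] = "avg"
    meta.index.name = "sample_id"
    collapsed.index = meta.index
    return SignalMatrix(matrix.mz_bins, collapsed, meta)


def select_strong_signals(matrix: SignalMatrix,
                          threshold_fraction: float = STRONG_SIGNAL_FRACTION) -> np.ndarray:
    """Indices of bins with sum I strictly greater than the threshold.

    The threshold is ``threshold_fraction`` (default 5%) of the largest
    per-bin summed intensity; the comparison is a strict inequality.
    """
    sums = matrix.sum_intensity
    if sums.size == 0:
        raise ValueError("empty signal matrix")
    return np.flatnonzero(sums > threshold_fraction * sums.max())


def screen_significance(matrix: SignalMatrix, alpha: float = 0.05,
                        fdr_on_pairwise: bool = False) -> pd.DataFrame:
    """Kruskal-Wallis + Dunn-Bonferroni screen over signal bins.

    Default order: Benjamini-Hochberg FDR across bins on the omnibus
    Kruskal-Wallis p-values, then Dunn pairwise tests with Bonferroni
    adjustment within each FDR-significant bin.  With
    ``fdr_on_pairwise=True`` the FDR is instead applied across the
    pooled pairwise Dunn p-values of all bins.
    """
    groups = matrix.sample_meta["group"]
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arr = matrix.intensities.to_numpy()
    masks = [(groups == g).to_numpy() for g in labels]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("every group needs at least 2 samples")

    kw_p = np.empty(arr.shape[1])
    kw_h = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        res = inference.kruskal_wallis([arr[m, j] for m in masks])
        kw_h[j], kw_p[j] = res.statistic, res.p_value

    rows = []
    if not fdr_on_pairwise:
        q = inference.bh_fdr(kw_p)
        for j in range(arr.shape[1]):
            sig_pairs = []
            pair_table = None
            if q[j] < alpha:
                pair_table = inference.dunn_bonferroni(
                    [arr[m, j] for m in masks], labels=labels)
                sig = pair_table[pair_table["adjusted_p"] < alpha]
                sig_pairs = [f"{a}/{b}" for a, b in zip(sig["group_a"], sig["group_b"])]
            rows.append({
                "bin": matrix.intensities.columns[j], "mz": float(matrix.mz_bins[j]),
                "kw_h": float(kw_h[j]), "kw_p": float(kw_p[j]), "kw_q": float(q[j]),
                "significant": bool(q[j] < alpha and len(sig_pairs) > 0),
                "significant_pairs": ";".join(sig_pairs),
            })
    else:
        all_pairs = []
        for j in range(arr.shape[1]):
            pt = inference.dunn_bonferroni([arr[m, j] for m in masks],
                                           labels=labels, adjust="none")
            pt["bin_pos"] = j
            all_pairs.append(pt)
        pooled = pd.concat(all_pairs, ignore_index=True)
        pooled["adjusted_p"] = inference.bh_fdr(pooled["p_value"].to_numpy())
        for j in range(arr.shape[1]):
            sub = pooled[pooled["bin_pos"] == j]
            sig = sub[sub["adjusted_p"] < alpha]
            sig_pairs = [f"{a}/{b}" for a, b in zip(sig["group_a"], sig["group_b"])]
            rows.append({
                "bin": matrix.intensities.columns[j], "mz": float(matrix.mz_bins[j]),
                "kw_h": float(kw_h[j]), "kw_p": float(kw_p[j]), "kw_q": math.nan,
                "significant": len(sig_pairs) > 0,
                "significant_pairs": ";".join(sig_pairs),
            })
    return pd.DataFrame(rows)


@dataclass
class PCASummary:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    flag: str = ""


def pca_summary(matrix: SignalMatrix, n_components: int | None = None,
                scale: bool = False) -> PCASummary:
    """Centered (optionally unit-variance-scaled) PCA of the signal matrix."""
    X = matrix.intensities.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    flag = ""
    if np.allclose(X, X[0]):
        flag = "degenerate: constant matrix, zero variance"
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xc)
    comp_names = [f"PC{i+1}" for i in range(pca.n_components_)]
    return PCASummary(
        scores=pd.DataFrame(scores, index=matrix.intensities.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=matrix.intensities.columns,
                              columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        flag=flag,
    )


@dataclass
class WardClustering:
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: np.ndarray
    col_order: np.ndarray
    row_clusters: np.ndarray
    scaled: pd.DataFrame


def ward_heatmap(matrix: SignalMatrix, n_row_clusters: int = 2) -> WardClustering:
    """Ward clustering of z-scaled signals with Euclidean distance.

    Each bin (column) is z-scored across samples, then rows and columns
    are clustered with Ward linkage on Euclidean distances.  Leaf order
    is made deterministic by optimal leaf ordering (tightest merges
    first).
    """
    X = matrix.intensities.to_numpy(dtype=float)
    if X.shape[0] < 2:
        return WardClustering(None, None, np.array([0]), np.arange(X.shape[1]),
                              np.array([1]), matrix.intensities.copy())
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    dr = pdist(Z, metric="euclidean")
    row_link = optimal_leaf_ordering(linkage(dr, method="ward"), dr)
    if X.shape[1] >= 2:
        dc = pdist(Z.T, metric="euclidean")
        col_link = optimal_leaf_ordering(linkage(dc, method="ward"), dc)
        col_order = leaves_list(col_link)
    else:
        col_link, col_order = None, np.arange(X.shape[1])
    return WardClustering(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=leaves_list(row_link),
        col_order=col_order,
        row_clusters=fcluster(row_link, t=n_row_clusters, criterion="maxclust"),
        scaled=pd.DataFrame(Z, index=matrix.intensities.index,
                            columns=matrix.intensities.columns),
    )


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula (most abundant isotopes)."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"unparsable formula: {formula!r}")
    mass = 0.0
    for elem, count in _FORMULA_RE.findall(formula):
        if not elem:
            continue
        if elem not in MONOISOTOPIC_MASSES:
            raise ValueError(f"unknown element {elem!r} in formula {formula!r}")
        mass += MONOISOTOPIC_MASSES[elem] * (int(count) if count else 1)
    return mass


def theoretical_adduct_mz(formula: str, adduct: str) -> float:
    """m/z of a singly charged cationic adduct of the neutral formula."""
    if adduct not in ADDUCT_MASSES:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_MASSES)}")
    return monoisotopic_mass(formula) + ADDUCT_MASSES[adduct]


def annotate_mass(query_mz: float, formula_table: pd.DataFrame,
                  adducts=None, tolerance_ppm: float = DEFAULT_TOLERANCE_PPM
                  ) -> list[AnnotationHit]:
    """Annotate a query m/z against a formula table within a ppm band.

    ``formula_table`` needs columns ``name`` and ``formula``; an
    optional ``adduct`` column restricts each entry to its own adduct,
    otherwise every adduct in ``adducts`` (default: all known cations)
    is tried.  Unparsable formulas are skipped with a logged warning;
    remaining entries are still processed.  Hits are sorted by |ppm|.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    hits: list[AnnotationHit] = []
    default_adducts = list(adducts) if adducts is not None else sorted(ADDUCT_MASSES)
    for _, row in formula_table.iterrows():
        row_adducts = [row["adduct"]] if "adduct" in row and pd.notna(row.get("adduct")) \
            else default_adducts
        try:
            m = monoisotopic_mass(str(row["formula"]))
        except ValueError as exc:
            logger.warning("annotate_mass: skipping %r: %s", row.get("name"), exc)
            continue
        for adduct in row_adducts:
            theo = m + ADDUCT_MASSES[adduct]
            ppm = (query_mz - theo) / theo * 1e6
            if abs(ppm) <= tolerance_ppm:
                hits.append(AnnotationHit(float(query_mz), str(row["name"]),
                                          str(row["formula"]), adduct,
                                          float(theo), float(ppm)))
    hits.sort(key=lambda h: abs(h.ppm_error))
    return hits


def load_bundled_annotation_table() -> pd.DataFrame:
    """Load the bundled table of tentative skeletal-muscle annotations.

    Columns: name, formula, adduct, printed_mz (the m/z value the
    annotation was reported at), note.  Two entries are known to miss
    their printed value at the default 10 ppm band (the sulfated
    xanthurenic acid sodium adducts); the ``note`` column records this
    rather than forcing agreement — the annotations are tentative.
    """
    ref = importlib.resources.files("glucodyn.data") / "annotation_table.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
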