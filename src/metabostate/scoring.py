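"""Transcriptome metabolic scoring.

Two complementary read-outs of a gene-expression matrix (genes x
samples, library-size-normalized log-scale values):

* **Activity signatures** for the master regulators pAMPK and HIF-1.
  Neither regulator's own mRNA reports its activity (AMPK acts through
  phosphorylation, HIF-1 through protein stabilization), so activity is
  inferred from downstream transcriptional targets: the target genes are
  standardized across samples and the first principal component of the
  samples-by-targets matrix is the signature, sign-oriented so that
  higher signature means higher mean target expression.

* **Pathway scores** for TCA, glycolysis and FAO enzyme sets: the mean
  z-score of the member enzyme genes per sample.  Higher score = higher
  inferred pathway activity.  The enzyme sets are disjoint from the
  signature target sets so the two read-outs are independent.

Both are used to place samples in the 2-D (AMPK, HIF-1) activity plane,
follow treated samples over time toward the metabolically inactive
low/low corner, and group cohorts into the four metabolic phenotypes.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

QUADRANT_NAMES = {
    (1, -1): "O-like",
    (-1, 1): "W-like",
    (1, 1): "hybrid",
    (-1, -1): "L/L-like",
}


@dataclass(frozen=True)
class GeneSets:
    """Named gene lists driving signatures and pathway scores."""

    ampk_targets: tuple[str, ...]
    hif1_targets: tuple[str, ...]
    tca_enzymes: tuple[str, ...]
    glycolysis_enzymes: tuple[str, ...]
    fao_enzymes: tuple[str, ...]

    def __post_init__(self) -> None:
        signature = set(self.ampk_targets) | set(self.hif1_targets)
        enzymes = (
            set(self.tca_enzymes) | set(self.glycolysis_enzymes) | set(self.fao_enzymes)
        )
        overlap = signature & enzymes
        if overlap:
            raise ValueError(
                "pathway enzyme sets must be disjoint from signature target "
                f"sets; overlap: {sorted(overlap)}"
            )

    @classmethod
    def from_gmt(cls, path=None) -> "GeneSets":
        """Load from a GMT file; with ``path=None`` the editable default
        lists shipped with the package are used."""
        if path is None:
            res = importlib.resources.files("metabostate.data").joinpath("genesets.gmt")
            path = str(res)
        sets = read_gmt(str(path))
        try:
            return cls(
                ampk_targets=tuple(sets["AMPK_TARGETS"]),
                hif1_targets=tuple(sets["HIF1_TARGETS"]),
                tca_enzymes=tuple(sets["TCA_ENZYMES"]),
                glycolysis_enzymes=tuple(sets["GLYCOLYSIS_ENZYMES"]),
                fao_enzymes=tuple(sets["FAO_ENZYMES"]),
            )
        except KeyError as exc:
            raise ValueError(f"GMT file missing required set: {exc}") from exc

    def to_gmt(self, path) -> None:
        rows = {
            "AMPK_TARGETS": self.ampk_targets,
            "HIF1_TARGETS": self.hif1_targets,
            "TCA_ENZYMES": self.tca_enzymes,
            "GLYCOLYSIS_ENZYMES": self.glycolysis_enzymes,
            "FAO_ENZYMES": self.fao_enzymes,
        }
        with open(path, "w") as fh:
            for name, genes in rows.items():
                fh.write("\t".join([name, "metabostate"] + list(genes)) + "\n")


def default_gene_sets() -> GeneSets:
    return GeneSets.from_gmt()


def read_expression(path, log2p1: bool = False) -> pd.DataFrame:
    """Read a genes x samples TSV/CSV (gene ids in the first column,
    sample ids in the header).  ``log2p1`` applies log2(x+1) for raw
    counts."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    expr = pd.read_csv(path, sep=sep, index_col=0)
    if expr.index.duplicated().any() or expr.columns.duplicated().any():
        raise ValueError("duplicated gene or sample identifiers")
    if log2p1:
        expr = np.log2(expr + 1.0)
    return expr


def _usable_genes(expr: pd.DataFrame, genes: Iterable[str], context: str) -> list[str]:
    genes = list(genes)
    present = [g for g in genes if g in expr.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.warning("%s: %d gene(s) absent from matrix, dropped: %s",
                       context, len(missing), missing)
    keep = []
    for g in present:
        if expr.loc[g].std(ddof=1) > 0:
            keep.append(g)
        else:
            logger.warning("%s: gene %s has zero variance across samples, dropped",
                           context, g)
    return keep


def _zscore_rows(sub: pd.DataFrame) -> pd.DataFrame:
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)   # sample sd: cohorts here are small
    return sub.sub(mu, axis=0).div(sd, axis=0)


def pathway_score(expr: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """Mean z-score of the member genes per sample:
    ``S_P = (1/n) * sum_i zscore(x_i)`` over the n listed genes found in
    the matrix.  Scores are centred (sum to zero across samples)."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score")
    keep = _usable_genes(expr, genes, "pathway_score")
    if not keep:
        raise ValueError("no usable (present, non-constant) genes in list")
    return _zscore_rows(expr.loc[keep]).mean(axis=0).rename("score")


@dataclass
class SignatureResult:
    """PC1 activity signature over a scoring cohort."""

    scores: pd.Series               # per-sample signature, zero mean
    variance_explained: float
    flipped: bool                   # True if PC1 was negated to orient
    n_genes: int


def activity_signature(expr: pd.DataFrame, targets: Sequence[str]) -> SignatureResult:
    """PC1 of the standardized downstream-target expression as the
    regulator's activity signature.

    The sign of a principal component is arbitrary, so the component is
    oriented to correlate positively with the mean standardized target
    expression: higher signature = more active regulator.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for a PC1 signature")
    keep = _usable_genes(expr, targets, "activity_signature")
    if len(keep) < 2:
        raise ValueError("need at least 2 usable target genes")
    Z = _zscore_rows(expr.loc[keep])
    X = Z.T.to_numpy()              # samples x genes
    pca = PCA(n_components=1).fit(X)
    scores = pca.transform(X)[:, 0]
    mean_expr = X.mean(axis=1)
    flipped = False
    r = np.corrcoef(scores, mean_expr)[0, 1]
    if r < 0:
        scores = -scores
        flipped = True
    return SignatureResult(
        scores=pd.Series(scores, index=expr.columns, name="signature"),
        variance_explained=float(pca.explained_variance_ratio_[0]),
        flipped=flipped,
        n_genes=len(keep),
    )


@dataclass
class TrajectoryResult:
    """Per-sample signatures plus per-subject direction-of-change flags."""

    table: pd.DataFrame             # sample, subject, time, ampk, hif1
    flags: pd.DataFrame             # subject x (ampk_decrease, hif1_decrease, both)
    both_decrease_count: int
    excluded_subjects: tuple[str, ...] = ()


def signature_trajectory(
    expr: pd.DataFrame,
    sample_meta: pd.DataFrame,
    gene_sets: GeneSets,
) -> TrajectoryResult:
    """Longitudinal AMPK/HIF-1 signatures per subject.

    Signatures are computed once on the pooled cohort (all samples of
    all subjects), then each subject's change is summarized as
    ``last - first`` along its time axis; a subject "decreases" on an
    axis when that difference is negative.  Subjects with fewer than two
    time points are excluded with a warning.

    ``sample_meta`` must be indexed by sample id with columns
    ``subject`` and ``time``.
    """
    missing = set(expr.columns) - set(sample_meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    ampk = activity_signature(expr, gene_sets.ampk_targets).scores
    hif1 = activity_signature(expr, gene_sets.hif1_targets).scores
    table = pd.DataFrame({
        "subject": sample_meta.loc[expr.columns, "subject"],
        "time": sample_meta.loc[expr.columns, "time"],
        "ampk": ampk,
        "hif1": hif1,
    })
    flags = {}
    excluded = []
    for subject, grp in table.groupby("subject", sort=True):
        grp = grp.sort_values("time")
        if len(grp) < 2:
            logger.warning("subject %s has a single time point; excluded", subject)
            excluded.append(str(subject))
            continue
        d_ampk = grp["ampk"].iloc[-1] - grp["ampk"].iloc[0]
        d_hif1 = grp["hif1"].iloc[-1] - grp["hif1"].iloc[0]
        flags[subject] = {
            "ampk_decrease": d_ampk < 0,
            "hif1_decrease": d_hif1 < 0,
            "both_decrease": (d_ampk < 0) and (d_hif1 < 0),
        }
    flags_df = pd.DataFrame(flags).T
    count = int(flags_df["both_decrease"].sum()) if len(flags_df) else 0
    return TrajectoryResult(
        table=table,
        flags=flags_df,
        both_decrease_count=count,
        excluded_subjects=tuple(excluded),
    )


@dataclass
class ClusterResult:
    labels: np.ndarray              # integer cluster id per sample
    quadrants: dict[int, str]       # cluster id -> quadrant annotation
    centroids: pd.DataFrame


def signature_clusters(
    signatures: pd.DataFrame, k: int = 4, seed: int = 0
) -> ClusterResult:
    """k-means in the 2-D (AMPK, HIF-1) signature plane, each cluster
    annotated by its centroid quadrant relative to the origin:
    (+,-) OXPHOS-like, (-,+) glycolysis-like, (+,+) hybrid,
    (-,-) low/low-like."""
    if len(signatures) < k:
        raise ValueError(f"need at least {k} samples")
    X = signatures.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all samples identical")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    centroids = pd.DataFrame(km.cluster_centers_, columns=list(signatures.columns))
    quadrants = {}
    for cid, (a, h) in enumerate(km.cluster_centers_):
        key = (1 if a > 0 else -1, 1 if h > 0 else -1)
        quadrants[cid] = QUADRANT_NAMES[key]
    return ClusterResult(labels=km.labels_.copy(), quadrants=quadrants,
                         centroids=centroids)
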