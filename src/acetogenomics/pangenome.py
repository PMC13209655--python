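"""Pan-genome content: frequency classes, accessory matrix, content tree.

Gene clusters are binned by the fraction of genomes carrying them using the
Roary threshold ladder (core >= 99%, soft-core >= 95%, shell >= 15%, cloud
< 15%).  The accessory (non-core) matrix supports genome-content distances
(Jaccard by default, Hamming optionally) and a neighbor-joining tree
summarizing overall gene-repertoire similarity rather than sequence
divergence.  Module-specific presence-absence views are exported for
heatmap rendering.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import nj

DEFAULT_THRESHOLDS = {"core": 0.99, "soft_core": 0.95, "shell": 0.15}
CLASS_ORDER = ("core", "soft_core", "shell", "cloud")


def classify(matrix: pd.DataFrame, thresholds: dict | None = None):
    """Frequency-class label per cluster and per-class counts.

    ``matrix`` is clusters x genomes with binary entries.  Frequency is the
    presence count divided by the number of genomes; the ladder assigns the
    highest class whose threshold is met.  Returns ``(labels, counts)``.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    if matrix.shape[1] < 2:
        raise ValueError("need at least two genomes")
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence-absence matrix must be binary")
    freq = values.sum(axis=1) / matrix.shape[1]
    labels = np.where(
        freq >= thresholds["core"], "core",
        np.where(freq >= thresholds["soft_core"], "soft_core",
                 np.where(freq >= thresholds["shell"], "shell", "cloud")),
    )
    labels = pd.Series(labels, index=matrix.index, name="class")
    counts = {c: int((labels == c).sum()) for c in CLASS_ORDER}
    return labels, counts


def accessory(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Non-core (shell + cloud) submatrix, row and column order preserved."""
    keep = ~labels.isin(["core", "soft_core"])
    return matrix.loc[keep[keep].index]


def content_distances(matrix: pd.DataFrame, metric: str = "jaccard") -> DistanceMatrix:
    """Pairwise genome-content distances between genome columns."""
    if metric not in ("jaccard", "hamming"):
        raise ValueError("metric must be 'jaccard' or 'hamming'")
    profiles = matrix.to_numpy().T.astype(bool)
    dm = squareform(pdist(profiles, metric=metric))
    return DistanceMatrix(dm, ids=list(matrix.columns))


def content_tree(matrix: pd.DataFrame, metric: str = "jaccard") -> str:
    """Unrooted neighbor-joining tree of genomes from the accessory matrix.

    Negative branch lengths produced by NJ on non-additive distances are
    clamped to zero.  Returns a Newick string.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least three genomes for a tree")
    tree = nj(content_distances(matrix, metric))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def module_view(matrix: pd.DataFrame, modules: dict):
    """Ordered presence-absence submatrix for module gene lists.

    ``modules`` maps module name -> list of cluster ids.  Returns
    ``(view, missing)`` where the view carries a ``module`` column and rows
    are ordered by module then by the given gene order; clusters absent
    from the matrix are listed in ``missing``.
    """
    rows, missing = [], []
    for module, genes in modules.items():
        for gene in genes:
            if gene in matrix.index:
                rows.append((module, gene))
            else:
                missing.append((module, gene))
    if not rows:
        return pd.DataFrame(columns=["module", *matrix.columns]), missing
    view = matrix.loc[[g for _, g in rows]].copy()
    view.insert(0, "module", [m for m, _ in rows])
    return view, missing


# Acid-tolerance gene modules rendered as presence-absence heatmaps.
DEFAULT_MODULES = {
    "efflux": ["oprM_1", "oprM_2", "oprM_3", "oprM_4", "oprM_5", "oprM_6",
               "yddA", "uup", "mdlB", "tagG"],
    "acetate_metabolism": ["acsA", "ackA", "pta", "aarC", "mqo", "acnA"],
    "chaperone_stress": ["groEL", "groES", "dnaK", "dnaJ", "grpE", "clpB",
                         "uvrA"],
    "ros_detox": ["srpA", "sodA", "katE"],
}


def read_roary(path: str) -> pd.DataFrame:
    """Binary matrix from a Roary gene_presence_absence.csv.

    Presence is any non-empty cell in a genome column (paralog columns
    collapse to one presence bit); the first 14 columns are Roary metadata.
    """
    df = pd.read_csv(path, index_col=0, low_memory=False)
    genome_cols = df.columns[13:]
    binary = df[genome_cols].notna() & (df[genome_cols].astype(str).str.strip() != "")
    return binary.astype(int)


def read_binary_csv(path: str) -> pd.DataFrame:
    """Plain binary presence-absence CSV (clusters x genomes)."""
    return pd.read_csv(path, index_col=0).astype(int)
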