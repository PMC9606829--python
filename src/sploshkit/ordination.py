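"""Ordination of presumed-pure accessions on SPLoSH(5 cM) profiles.

Raw SNP matrices over-weight well-assayed chromosomes and ignore linkage;
using each accession's vector of SPLoSH(5 cM) sums against the other wild
accessions as its feature row sidesteps both.  PCA on those rows
separates the species clusters; accessions falling outside their labeled
cluster (robust Mahalanobis distance beyond a chi-square quantile on the
leading components) are flagged as possible hybrids/admixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .model import GenotypePanel
from .pedigree import ImputedParent
from .segments import SploshMatrix

log = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray              # individuals x components
    variance_explained: np.ndarray       # non-increasing

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def pca_on_splosh(splosh5: SploshMatrix, subset_ids: list[str],
                  feature_ids: list[str] | None = None,
                  n_components: int | None = None) -> OrdinationResult:
    """PCA of SPLoSH(5 cM) rows for a subset of accessions.

    ``feature_ids`` are the matrix columns used as features; by default
    the subset itself (wild-vs-wild sharing profiles).  Columns are
    mean-centered by the decomposition.
    """
    if len(subset_ids) < 3:
        raise ValueError("ordination needs at least 3 individuals")
    feats = feature_ids if feature_ids is not None else subset_ids
    rows = np.array([[splosh5.value(i, f) for f in feats] for i in subset_ids])
    k = n_components or min(10, len(subset_ids) - 1, rows.shape[1])
    k = min(k, len(subset_ids) - 1, rows.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(rows)
    return OrdinationResult(list(subset_ids), coords,
                            pca.explained_variance_ratio_)


def substitute_imputed_parents(panel: GenotypePanel,
                               family_specs: dict[str, list[str]],
                               imputed_parents: dict[str, ImputedParent],
                               ordination_ids: list[str] | None = None
                               ) -> tuple[GenotypePanel, list[str]]:
    """Replace full-sib groups by their (possibly imputed) parents.

    Large full-sib families drag ordination toward family clusters rather
    than species clusters; each declared family's members are removed from
    the ordination subset and any imputed parent profiles are added to the
    panel as ordinary individuals (unresolved SNPs become missing calls).
    Returns the augmented panel and the adjusted ordination id list.
    """
    subset = list(ordination_ids if ordination_ids is not None else panel.ids)
    out = panel
    drop: set[str] = set()
    for fam, members in family_specs.items():
        for m in members:
            if m not in panel._row:
                warnings.warn(f"family {fam!r}: member {m!r} not in panel; "
                              "skipped")
                continue
            drop.add(m)
    subset = [i for i in subset if i not in drop]
    for pid, imp in imputed_parents.items():
        if pid not in out._row:
            out = out.with_individual(pid, "imputed_parent", "wild",
                                      imp.genotypes)
        if pid not in subset:
            subset.append(pid)
    return out, subset


def _robust_d2(x: np.ndarray, cluster: np.ndarray) -> np.ndarray:
    """Squared robust distance: median center, MAD-scaled per component.

    PCA coordinates are orthogonal, so a diagonal scaling suffices;
    median/MAD have a 50% breakdown point, keeping a few admixed
    individuals mislabeled into a cluster from masking themselves.
    """
    med = np.median(cluster, axis=0)
    mad = np.median(np.abs(cluster - med), axis=0) * 1.4826
    return (((x - med) / (mad + 1e-12)) ** 2).sum(axis=-1)


@lru_cache(maxsize=64)
def _null_cutoff(n: int, k: int, quantile: float, n_sim: int = 1000,
                 seed: int = 20_240_101) -> float:
    """Null quantile of within-cluster robust distances.

    At genebank cluster sizes the chi-square approximation to the robust
    distance is miscalibrated (the median/MAD estimation noise dominates),
    so the cutoff is calibrated by Monte Carlo on standard-normal clusters
    of the same size and dimension.
    """
    rng = np.random.default_rng(seed)
    dists = [_robust_d2(x, x) for x in rng.standard_normal((n_sim, n, k))]
    return float(np.quantile(np.concatenate(dists), quantile))


def flag_outliers(ordination: OrdinationResult, species_labels: dict[str, str],
                  quantile: float = 0.995, n_components: int = 2,
                  min_cluster: int = 4) -> pd.DataFrame:
    """Flag accessions far outside their labeled species cluster.

    Per species, a robust center and spread (median and scaled MAD per
    component) are estimated on the first ``n_components`` coordinates;
    squared robust distances beyond the Monte-Carlo-calibrated null
    ``quantile`` flag the accession as a possible hybrid/admixed outlier.
    Clusters smaller than ``min_cluster`` and degenerate (zero-spread)
    clusters are skipped.
    """
    if len({species_labels[i] for i in ordination.ids if i in species_labels}) < 2:
        raise ValueError("need at least 2 labeled species clusters")
    k = min(n_components, ordination.coordinates.shape[1])
    coords = ordination.coordinates[:, :k]
    rows = []
    labels = pd.Series({i: species_labels.get(i, "") for i in ordination.ids})
    for sp in sorted(set(labels) - {""}):
        members = np.array([i for i, l in labels.items() if l == sp])
        idx = [ordination.ids.index(m) for m in members]
        x = coords[idx]
        if len(members) < min_cluster:
            warnings.warn(f"species cluster {sp!r} has {len(members)} members "
                          f"(< {min_cluster}); outlier check skipped")
            for m in members:
                rows.append((m, sp, np.nan, False))
            continue
        if np.allclose(x.std(axis=0), 0.0):
            for m in members:
                rows.append((m, sp, 0.0, False))
            continue
        cutoff = _null_cutoff(len(members), k, quantile)
        d2 = _robust_d2(x, x)
        for m, dd in zip(members, d2):
            rows.append((m, sp, float(dd), bool(dd > cutoff)))
    return pd.DataFrame(rows, columns=["id", "species", "mahalanobis_sq",
                                       "flagged"]).set_index("id")
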