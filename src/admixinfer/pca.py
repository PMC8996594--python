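"""PCA of genotype matrices with least-squares projection of extra samples.

Sites are centred at twice the fitted-panel allele frequency and, in the
default Patterson normalization, scaled by sqrt(p(1-p)); the decomposition is
an SVD of the resulting samples-by-sites matrix.  Component signs are fixed
by making each component's largest-magnitude site loading positive, so
results are deterministic.

Held-out or low-coverage samples are *projected*: each sample's coordinates
solve the least-squares problem restricted to its own non-missing sites
("lsqproject" behaviour), which is what makes projecting a 0.03X
pseudo-haploid genome meaningful.  Pseudo-haploid {0, 2} calls are used as-is;
the known consequence is a shrinkage of projected coordinates toward the
origin that grows as coverage drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

__all__ = ["PCAModel", "fit_pca", "project"]

MIN_OVERLAP = 100


@dataclass
class PCAModel:
    """Fitted PCA: per-site centring/scaling, loadings, eigenvalues, scores."""

    sites: pd.DataFrame            # chrom, pos of the model's site set
    means: np.ndarray              # 2 * p_hat per site
    scales: np.ndarray             # per-site normalization divisor
    loadings: np.ndarray           # (n_sites, k), orthonormal columns
    eigenvalues: np.ndarray        # (k,)
    samples: list[str]
    coordinates: pd.DataFrame      # fitted-sample scores (samples x PCs)
    normalization: str = "patterson"

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def project(self, gm_new: GenotypeMatrix) -> pd.DataFrame:
        """Project new samples onto the fitted axes (missing-data aware).

        Sites are matched on (chrom, pos); each sample's coordinates are the
        least-squares fit of its centred, scaled calls onto the loadings
        restricted to its non-missing sites.  Rows carry ``n_sites_used`` and
        a ``low_overlap`` flag (< 100 usable sites).
        """
        key_model = pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]])
        key_new = pd.MultiIndex.from_frame(gm_new.sites[["chrom", "pos"]])
        model_idx = key_model.get_indexer(key_new)
        usable = model_idx >= 0
        rows = []
        for j, s in enumerate(gm_new.samples):
            called = (gm_new.calls[:, j] != MISSING) & usable
            mi = model_idx[called]
            y = (gm_new.calls[called, j] - self.means[mi]) / self.scales[mi]
            L = self.loadings[mi]
            n_used = int(called.sum())
            if n_used == 0:
                coords = np.full(self.k, np.nan)
            else:
                coords, *_ = np.linalg.lstsq(L, y, rcond=None)
            rows.append([s, *coords, n_used, n_used < MIN_OVERLAP])
        cols = ["sample"] + [f"PC{i + 1}" for i in range(self.k)] \
            + ["n_sites_used", "low_overlap"]
        return pd.DataFrame(rows, columns=cols).set_index("sample")

    def coordinates_tsv(self, path) -> None:
        out = self.coordinates.copy()
        out["n_sites_used"] = len(self.sites)
        out["projected"] = False
        out.to_csv(path, sep="\t")


def fit_pca(gm: GenotypeMatrix, k: int = 10, normalization: str = "patterson",
            mean_impute: bool = False) -> PCAModel:
    """Fit a PCA on a fully called genotype panel.

    ``normalization='patterson'`` scales each site by sqrt(p(1-p)) (drift
    units); ``'unit'`` leaves sites unscaled.  Missing calls are only allowed
    with ``mean_impute=True``.  Needs at least 3 samples; k is capped at
    min(n_samples - 1, n_sites).
    """
    if gm.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    if normalization not in ("patterson", "unit"):
        raise ValueError(f"unknown normalization {normalization!r}")
    X = gm.calls.astype(float)
    miss = gm.calls == MISSING
    if miss.any():
        if not mean_impute:
            raise ValueError(
                "missing calls among fitted samples (set mean_impute=True)"
            )
        X[miss] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=1) / 2.0
    means = 2.0 * p
    if normalization == "patterson":
        scales = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
    else:
        scales = np.ones_like(p)
    Xc = (X - means[:, None]) / scales[:, None]
    Xc[np.isnan(Xc)] = 0.0  # mean-imputed entries contribute nothing
    k = min(k, gm.n_samples - 1, gm.n_sites)
    # samples x sites; drop the trivial constant direction via economy SVD
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic signs: largest-|loading| entry of each component positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    coords = U * S
    coordinates = pd.DataFrame(
        coords, index=gm.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCAModel(
        sites=gm.sites[["chrom", "pos"]].copy(),
        means=means,
        scales=scales,
        loadings=Vt.T,
        eigenvalues=S**2 / max(gm.n_samples - 1, 1),
        samples=list(gm.samples),
        coordinates=coordinates,
        normalization=normalization,
    )


def project(model: PCAModel, gm_new: GenotypeMatrix) -> pd.DataFrame:
    """Functional alias for :meth:`PCAModel.project`."""
    return model.project(gm_new)


def plot_pca(coordinates: pd.DataFrame, x: str = "PC1", y: str = "PC2",
             labels: dict | None = None, ax=None):
    """Scatter of PCA coordinates, one point per sample (matplotlib).

    ``labels`` maps sample name to a group label used for colouring;
    unlisted samples share one group.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    labels = labels or {}
    groups: dict[str, list[str]] = {}
    for s in coordinates.index:
        groups.setdefault(labels.get(s, "sample"), []).append(s)
    for grp, names in sorted(groups.items()):
        sub = coordinates.loc[names]
        ax.scatter(sub[x], sub[y], label=grp, s=25)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(fontsize=8)
    return ax
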