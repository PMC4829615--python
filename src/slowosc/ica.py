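"""Group spatial ICA: two-stage PCA, Infomax, GICA back-reconstruction.

The estimation problem: each subject's preprocessed scan X_i
(time x voxels) is reduced to ``subject_pca_dim`` temporal principal
components; the reduced matrices are concatenated along the (reduced)
time axis and a second, group-level PCA brings the stack down to
``n_components`` whitened rows over voxels.  Spatial Infomax ICA then
rotates those rows into maximally independent spatial maps (voxels are
the i.i.d. samples; time courses form the mixing matrix).  Subject
time courses and maps come back out through the GICA chain: the group
mixing matrix is partitioned per subject and lifted through each
subject's retained PCA basis.

Model usage follows the estimator/results convention::

    model = GroupICA(scans, GroupICAConfig(n_components=8, seed=0))
    res = model.fit()                      # GroupICAResults
    res.group_maps, res.subject_timecourses
    res.stability_index                    # after model.fit(stability=True)
    assign = res.match_templates(templates)
    res.summary()

Infomax here is the natural-gradient logistic-nonlinearity variant with
learning-rate annealing on divergence; it recovers super-Gaussian
(sparse) spatial sources, which network maps are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .bands import BandScheme
from .exceptions import ConvergenceError, ParameterError, ValidationError
from .simulate import CohortScan
from . import spectra as _spectra

__all__ = [
    "GroupICAConfig",
    "GroupICA",
    "GroupICAResults",
    "ComponentAssignment",
    "temporal_concat_pca",
    "infomax_unmix",
    "gica_backreconstruct",
    "stability_resample",
    "match_templates",
    "robustness_filter",
]

ROBUSTNESS_THRESHOLD = 50.0  # LF/HF power ratio a component must exceed


@dataclass(frozen=True)
class GroupICAConfig:
    n_components: int = 28
    subject_pca_dim: int | None = None  # default 1.5 x n_components
    max_iter: int = 512
    learning_rate: float = 0.01
    tol: float = 1e-6
    n_stability_runs: int = 20
    seed: int = 0

    def resolved_pca_dim(self) -> int:
        return self.subject_pca_dim or int(round(1.5 * self.n_components))


@dataclass(frozen=True)
class ComponentAssignment:
    """Mapping of recovered components to named network templates."""

    labels: dict[int, str]  # component index -> network label
    correlations: dict[int, float]
    unassigned_templates: tuple[str, ...]

    def index_of(self, label: str) -> int | None:
        for idx, lab in self.labels.items():
            if lab == label:
                return idx
        return None


# ---------------------------------------------------------------------------
# stage functions

def _subject_matrix(scan: CohortScan | np.ndarray) -> np.ndarray:
    """Time x voxels matrix, voxel-wise demeaned."""
    data = scan.data if isinstance(scan, CohortScan) else np.asarray(scan, float)
    X = data.T.astype(float)  # (time, voxels)
    return X - X.mean(axis=0, keepdims=True)


def temporal_concat_pca(
    scans: Sequence[CohortScan | np.ndarray], cfg: GroupICAConfig
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, np.ndarray]:
    """Two-stage temporal reduction.

    Returns ``(group_reduced, subject_bases, group_basis, singvals)``:

    * ``group_reduced`` — (n_components x voxels) whitened group rows;
    * ``subject_bases`` — per subject the (time x d) orthonormal temporal
      basis U_i with X_i ~ U_i R_i;
    * ``group_basis`` — ((n*d) x k) group reduction with
      stack(R_i) ~ group_basis @ diag(singvals) @ group_reduced.
    """
    k = cfg.n_components
    d = cfg.resolved_pca_dim()
    if not scans:
        raise ValidationError("no scans")
    reduced, bases = [], []
    for i, scan in enumerate(scans):
        X = _subject_matrix(scan)
        if d > min(X.shape):
            raise ParameterError(
                f"subject_pca_dim={d} exceeds data rank bound {min(X.shape)}"
            )
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        # demeaning over time costs one rank; anything below that is a
        # genuinely degenerate subject
        rank = int(np.sum(s > s[0] * 1e-12)) if s[0] > 0 else 0
        if rank < min(d, X.shape[0] - 1, X.shape[1]):
            sid = scan.subject_id if isinstance(scan, CohortScan) else f"#{i}"
            raise ValidationError(f"subject {sid}: data rank-deficient below {d}")
        bases.append(U[:, :d])
        reduced.append(s[:d, None] * Vt[:d])  # (d, voxels)
    stack = np.vstack(reduced)  # (n*d, voxels)
    Ug, sg, Vgt = np.linalg.svd(stack, full_matrices=False)
    if k > len(sg):
        raise ParameterError(f"n_components={k} exceeds group rank {len(sg)}")
    # whitened group rows: unit variance over voxels
    nv = stack.shape[1]
    group_reduced = Vgt[:k] * np.sqrt(nv)
    return group_reduced, bases, Ug[:, :k], sg[:k]


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    np.negative(np.abs(u), out=out)
    np.exp(out, out=out)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + out[pos])
    out[~pos] = out[~pos] / (1.0 + out[~pos])
    return out


def infomax_unmix(
    reduced: np.ndarray,
    cfg: GroupICAConfig,
    rng: np.random.Generator | None = None,
    batch: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Natural-gradient Infomax on whitened rows; returns (W, maps).

    Update per voxel batch u = W x:  W += lr * (I + (1 - 2*sigma(u)) u^T) W.
    On divergence (non-finite or exploding weights) the learning rate is
    halved and estimation restarts; repeated failure raises.  Output maps
    are unit-variance rows oriented to positive skewness.
    """
    k, nv = reduced.shape
    if np.linalg.matrix_rank(reduced) < k:
        raise ValidationError("reduced matrix is not full rank")
    rng = rng or np.random.default_rng(cfg.seed)
    # random orthonormal init keeps whitening; identity is a valid draw
    A = rng.normal(size=(k, k))
    Q, _ = np.linalg.qr(A)
    lr = cfg.learning_rate
    for attempt in range(12):
        W = Q.copy()
        eye = np.eye(k)
        diverged = False
        order = np.arange(nv)
        for it in range(cfg.max_iter):
            rng.shuffle(order)
            max_delta = 0.0
            for start in range(0, nv, batch):
                idx = order[start : start + batch]
                u = W @ reduced[:, idx]
                y = _sigmoid(u)
                dW = lr * ((eye + (1.0 - 2.0 * y) @ u.T / len(idx)) @ W)
                W += dW
                md = np.max(np.abs(dW))
                if not np.isfinite(md) or np.max(np.abs(W)) > 1e8:
                    diverged = True
                    break
                max_delta = max(max_delta, md)
            if diverged:
                break
            if max_delta < cfg.tol * max(1.0, np.max(np.abs(W))):
                break
        if not diverged:
            break
        lr *= 0.5
    else:
        raise ConvergenceError("Infomax diverged at every annealed learning rate")
    maps = W @ reduced
    # unit-variance rows, oriented to positive skewness; scale/sign folded
    # into W so maps == W @ reduced always holds
    sd = maps.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    skew_sign = np.sign(((maps / sd[:, None]) ** 3).mean(axis=1))
    skew_sign[skew_sign == 0] = 1.0
    scale = skew_sign / sd
    W = W * scale[:, None]
    maps = maps * scale[:, None]
    return W, maps


def gica_backreconstruct(
    maps: np.ndarray,
    W: np.ndarray,
    subject_bases: Sequence[np.ndarray],
    group_basis: np.ndarray,
    singvals: np.ndarray,
    scans: Sequence[CohortScan | np.ndarray],
    n_voxels: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject time courses and maps through the GICA chain.

    With stack(R_i) ~ G diag(s) H and maps S = W H, the concatenated
    mixing is M = G diag(s) W^{-1} / sqrt(nv); its per-subject partition
    M_i (d x k) lifts to time courses TC_i = U_i M_i, and subject maps
    are S_i = pinv(M_i) R_i.
    """
    d = subject_bases[0].shape[1]
    # stack = G diag(s) Vgt = (G diag(s)/sqrt(nv)) H and H = W^{-1} S,
    # so the concatenated mixing is M = G diag(s) W^{-1} / sqrt(nv)
    mixing = group_basis @ (singvals[:, None] * np.linalg.inv(W)) / np.sqrt(n_voxels)
    tcs, smaps = [], []
    for i, (U, scan) in enumerate(zip(subject_bases, scans)):
        Mi = mixing[i * d : (i + 1) * d]  # (d, k)
        tcs.append(U @ Mi)  # (time, k)
        X = _subject_matrix(scan)
        Ri = U.T @ X  # (d, voxels)
        smaps.append(np.linalg.pinv(Mi) @ Ri)  # (k, voxels)
    return np.stack(tcs), np.stack(smaps)


def _abs_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|Pearson r| between rows of a and rows of b."""
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return np.abs(az @ bz.T) / a.shape[1]


def stability_resample(
    scans: Sequence[CohortScan | np.ndarray],
    cfg: GroupICAConfig,
    reference_maps: np.ndarray | None = None,
) -> np.ndarray:
    """ICASSO-style reproducibility index per component.

    Reruns the group ICA ``n_stability_runs`` times under random
    initialisation and subject-level bootstrap, pools all runs'
    components, clusters them by average-linkage on the 1 - |r| spatial
    distance, and scores each cluster as (mean intra-cluster |r|) minus
    (mean |r| to components outside the cluster), clipped to [0, 1].
    Indices are reported in the order of ``reference_maps`` (the main
    fit), which join the clustering as anchor members.
    """
    if cfg.n_stability_runs < 2:
        raise ParameterError("n_stability_runs must be >= 2")
    rng = np.random.default_rng(cfg.seed + 1)
    if reference_maps is None:
        red, *_ = temporal_concat_pca(scans, cfg)
        _, reference_maps = infomax_unmix(red, cfg, rng=np.random.default_rng(cfg.seed))
    all_maps = [reference_maps]
    n = len(scans)
    for _ in range(cfg.n_stability_runs):
        pick = rng.integers(0, n, size=n)  # bootstrap subjects
        boot = [scans[j] for j in pick]
        try:
            red, *_ = temporal_concat_pca(boot, cfg)
            _, maps = infomax_unmix(red, cfg, rng=rng)
        except (ValidationError, ConvergenceError):
            continue  # degenerate resample: skip this run
        all_maps.append(maps)
    pool = np.vstack(all_maps)
    sim = _abs_corr(pool, pool)
    np.clip(sim, 0.0, 1.0, out=sim)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    k = reference_maps.shape[0]
    # cut at |r| = 0.5: reproducible components recur across runs at much
    # higher similarity, while unstable ones scatter into small clusters
    clusters = fcluster(Z, t=0.5, criterion="distance")
    index = np.zeros(k)
    for i in range(k):
        c = clusters[i]  # cluster containing reference component i
        members = clusters == c
        if members.sum() > 1:
            intra = (sim[members][:, members].sum() - members.sum()) / (
                members.sum() * (members.sum() - 1)
            )
        else:
            intra = 0.0
        extra = sim[members][:, ~members].mean() if (~members).any() else 0.0
        index[i] = np.clip(intra - extra, 0.0, 1.0)
    return index


def match_templates(
    group_maps: np.ndarray,
    templates: Mapping[str, np.ndarray],
    threshold: float = 0.3,
) -> tuple[ComponentAssignment, np.ndarray]:
    """Greedy template matching by descending |spatial correlation|.

    Each template and each component is used at most once; assigned maps
    are sign-flipped so their correlation with the template is positive.
    Templates whose best remaining correlation falls below ``threshold``
    stay unassigned.  Returns the assignment and the (possibly
    sign-flipped) maps.
    """
    labels = list(templates)
    tmpl = np.vstack([np.asarray(templates[l], float).ravel() for l in labels])
    if tmpl.shape[1] != group_maps.shape[1]:
        raise ValidationError("templates not on the component grid")
    az = (group_maps - group_maps.mean(axis=1, keepdims=True))
    az /= np.where(az.std(axis=1, keepdims=True) == 0, 1, az.std(axis=1, keepdims=True))
    bz = (tmpl - tmpl.mean(axis=1, keepdims=True))
    bz /= np.where(bz.std(axis=1, keepdims=True) == 0, 1, bz.std(axis=1, keepdims=True))
    corr = (bz @ az.T) / group_maps.shape[1]  # (templates, components)
    maps = group_maps.copy()
    assigned: dict[int, str] = {}
    corrs: dict[int, float] = {}
    used_t: set[int] = set()
    used_c: set[int] = set()
    flat = [(-abs(corr[ti, ci]), ti, ci) for ti in range(len(labels)) for ci in range(maps.shape[0])]
    for negr, ti, ci in sorted(flat):
        if ti in used_t or ci in used_c or -negr < threshold:
            continue
        used_t.add(ti)
        used_c.add(ci)
        assigned[ci] = labels[ti]
        corrs[ci] = float(abs(corr[ti, ci]))
        if corr[ti, ci] < 0:
            maps[ci] = -maps[ci]
    unassigned = tuple(l for i, l in enumerate(labels) if i not in used_t)
    return ComponentAssignment(assigned, corrs, unassigned), maps


def robustness_filter(
    subject_timecourses: np.ndarray,
    tr: float,
    scheme: BandScheme,
    threshold: float = ROBUSTNESS_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral robustness: mean LF/HF power ratio must exceed 50.

    ``subject_timecourses`` is (subjects, time, components).  Power is
    the squared raw amplitude spectrum summed over the low-frequency
    (0.01-0.1 Hz) and high-frequency (0.1 Hz-Nyquist) bands.  A subject
    with zero HF power contributes an infinite ratio (trivially robust).
    Returns (robust flags, mean ratios).
    """
    if "hf" not in scheme:
        k = subject_timecourses.shape[-1]
        return np.ones(k, bool), np.full(k, np.inf)
    n_sub, T, k = subject_timecourses.shape
    freqs = np.fft.rfftfreq(T, d=tr)
    lf_mask = scheme["lf"].mask(freqs)
    hf_mask = scheme["hf"].mask(freqs)
    ratios = np.zeros((n_sub, k))
    for s in range(n_sub):
        power = np.abs(np.fft.rfft(subject_timecourses[s], axis=0)) ** 2
        lf = power[lf_mask].sum(axis=0)
        hf = power[hf_mask].sum(axis=0)
        with np.errstate(divide="ignore"):
            ratios[s] = np.where(hf > 0, lf / np.where(hf > 0, hf, 1.0), np.inf)
    mean_ratio = ratios.mean(axis=0)
    return mean_ratio > threshold, mean_ratio


# ---------------------------------------------------------------------------
# model / results

class GroupICA:
    """Group spatial ICA model over a cohort of scans."""

    def __init__(self, scans: Sequence[CohortScan | np.ndarray], config: GroupICAConfig | None = None):
        if not scans:
            raise ValidationError("empty cohort")
        self.scans = list(scans)
        self.config = config or GroupICAConfig()
        nvox = {s.n_voxels if isinstance(s, CohortScan) else np.asarray(s).shape[0] for s in self.scans}
        if len(nvox) != 1:
            raise ValidationError("scans are not on a common voxel grid")
        self.n_voxels = nvox.pop()

    @classmethod
    def from_cohort(cls, scans: Sequence[CohortScan], **config_kwargs) -> "GroupICA":
        return cls(scans, GroupICAConfig(**config_kwargs))

    def fit(self, stability: bool = False) -> "GroupICAResults":
        cfg = self.config
        reduced, bases, G, s = temporal_concat_pca(self.scans, cfg)
        W, maps = infomax_unmix(reduced, cfg, rng=np.random.default_rng(cfg.seed))
        tcs, smaps = gica_backreconstruct(
            maps, W, bases, G, s, self.scans, self.n_voxels
        )
        var_exp = self._variance_explained(s)
        stab = None
        if stability:
            stab = stability_resample(self.scans, cfg, reference_maps=maps)
        return GroupICAResults(
            model=self,
            group_maps=maps,
            unmixing=W,
            subject_timecourses=tcs,
            subject_maps=smaps,
            variance_explained=var_exp,
            stability_index=stab,
        )

    def _variance_explained(self, group_singvals: np.ndarray) -> float:
        """Fraction of total (demeaned) data variance carried by the final
        k-dimensional group subspace: the energy of the retained group
        singular values over the energy of the raw subject matrices."""
        total = sum(float((_subject_matrix(sc) ** 2).sum()) for sc in self.scans)
        kept = float((group_singvals**2).sum())
        return kept / total if total > 0 else 0.0


@dataclass
class GroupICAResults:
    """Fitted group ICA: maps, per-subject back-reconstructions, diagnostics."""

    model: GroupICA
    group_maps: np.ndarray  # (k, voxels), unit variance rows
    unmixing: np.ndarray  # (k, k)
    subject_timecourses: np.ndarray  # (subjects, time, k)
    subject_maps: np.ndarray  # (subjects, k, voxels)
    variance_explained: float
    stability_index: np.ndarray | None = None
    assignment: ComponentAssignment | None = None

    @property
    def n_components(self) -> int:
        return self.group_maps.shape[0]

    def match_templates(self, templates: Mapping[str, np.ndarray], threshold: float = 0.3) -> ComponentAssignment:
        """Identify components against named network templates (in place)."""
        assign, maps = match_templates(self.group_maps, templates, threshold)
        self.group_maps = maps
        self.assignment = assign
        return assign

    def robustness(self, scheme: BandScheme, tr: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        tr = tr or getattr(self.model.scans[0], "tr_seconds", None)
        if tr is None:
            raise ParameterError("tr required when scans carry no TR")
        return robustness_filter(self.subject_timecourses, tr, scheme)

    def component_spectra(
        self, tr: float | None = None, sigma_bins: float = 2.0, groups: Mapping[str, str] | None = None
    ) -> list[_spectra.ComponentSpectrum]:
        """Smoothed amplitude spectra of every subject x assigned component."""
        tr = tr or getattr(self.model.scans[0], "tr_seconds", None)
        if tr is None:
            raise ParameterError("tr required when scans carry no TR")
        labels = self.assignment.labels if self.assignment else {
            i: f"ic{i:02d}" for i in range(self.n_components)
        }
        out = []
        for si, scan in enumerate(self.model.scans):
            sid = scan.subject_id if isinstance(scan, CohortScan) else f"subj{si:03d}"
            for ci, lab in labels.items():
                spec = _spectra.amplitude_spectrum(
                    self.subject_timecourses[si, :, ci] - self.subject_timecourses[si, :, ci].mean(),
                    tr,
                    subject_id=sid,
                    component=lab,
                )
                out.append(_spectra.smooth_spectrum(spec, sigma_bins))
        return out

    def summary(self) -> str:
        lines = [
            "Group spatial ICA (Infomax, GICA back-reconstruction)",
            f"  subjects: {len(self.model.scans)}   voxels: {self.model.n_voxels}",
            f"  components: {self.n_components}   "
            f"subject PCA dim: {self.model.config.resolved_pca_dim()}",
            f"  variance explained: {self.variance_explained * 100:.1f}%",
        ]
        if self.stability_index is not None:
            lines.append(
                "  stability index: "
                + " ".join(f"{v:.2f}" for v in self.stability_index)
            )
        if self.assignment is not None:
            for ci in sorted(self.assignment.labels):
                lines.append(
                    f"  IC{ci:02d} -> {self.assignment.labels[ci]:<8s} "
                    f"(r = {self.assignment.correlations[ci]:+.3f})"
                )
            if self.assignment.unassigned_templates:
                lines.append(
                    "  unassigned templates: "
                    + ", ".join(self.assignment.unassigned_templates)
                )
        return "\n".join(lines)
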