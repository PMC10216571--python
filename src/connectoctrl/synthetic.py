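"""Group-structured synthetic SC and FC connectomes.

The patient data behind the study design is not public, so this module
produces surrogate inputs with the statistical properties the analysis
assumes:

* FC matrices come from a latent-factor time-series model.  Each node's
  signal is a loading vector times shared factors plus independent noise;
  the sample Pearson correlation of such series is a valid correlation
  matrix (symmetric PSD, unit diagonal) by construction, and is stored
  Fisher-z transformed with a zero diagonal, as the analysis expects.
* SC matrices are sparse symmetric non-negative weight matrices: Bernoulli
  edge presence (denser within than between hemispheres), gamma-distributed
  weights (right-skewed, like streamline-count ratios), repaired to a
  connected positive-weight graph when needed.

The group effect is a global attenuation of coupling — factor loadings for
FC, edge weights for SC — ordered control (1.0) > IDHmut > IDHwt, which
encodes the study's direction of effect: globally weakened connectivity in
patients, more so in the prognostically less favorable IDH-wildtype group.
Optionally a per-group lesion halves the coupling of selected nodes.

The structural base (SC topology and base weights, FC factor loadings) is
derived from the seed and modality alone, so that the same seed yields the
same underlying network across groups and the attenuation ratio is exactly
recoverable edge by edge; group identity enters through attenuation,
lesions, and (for FC) the group's own time-series noise.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import ConnectivityMatrix, RoiLabelSet, default_dmn_labels

__all__ = [
    "GeneratorConfig",
    "generate_fc_matrix",
    "generate_sc_matrix",
    "generate_study_set",
    "GROUPS",
]

GROUPS = ("control", "IDHmut", "IDHwt")

# sub-stream tags for deterministic, independently regenerable draws
_STREAM_SC_BASE = 101
_STREAM_SC_REPAIR = 102
_STREAM_FC_LOADINGS = 201
_STREAM_FC_NOISE = 202


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable parameters of the synthetic connectome generator.

    ``group_attenuation`` maps each group to a multiplier in (0, 1] applied
    to the coupling strength; the control group is the unattenuated
    reference.  ``lesion_nodes`` optionally maps a group to ROI labels whose
    coupling is additionally halved.
    """

    n_nodes: int = 26
    seed: int = 0
    group_attenuation: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "IDHmut": 0.8, "IDHwt": 0.6}
    )
    sc_density: float = 0.5
    fc_latent_factors: int = 5
    noise_sd: float = 0.1
    lesion_nodes: Optional[Mapping[str, Sequence[int]]] = None
    n_timepoints: int = 500
    sc_gamma_shape: float = 2.0
    sc_gamma_scale: float = 1.0
    intra_hemisphere_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        att = dict(self.group_attenuation)
        object.__setattr__(self, "group_attenuation", att)
        for g, a in att.items():
            if not (0.0 < a <= 1.0):
                raise ValueError(f"attenuation for {g!r} must lie in (0, 1]")
        if "control" in att and att["control"] != 1.0:
            raise ValueError("control attenuation must be 1.0")
        if "IDHmut" in att and "IDHwt" in att and att["IDHwt"] > att["IDHmut"]:
            raise ValueError("IDHwt attenuation must not exceed IDHmut")
        if not (0.0 < self.sc_density <= 1.0):
            raise ValueError("sc_density must lie in (0, 1]")
        if not (1 <= self.fc_latent_factors < self.n_nodes):
            raise ValueError("fc_latent_factors must satisfy 1 <= k < n_nodes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.lesion_nodes is not None:
            labset = set(self.labels().labels)
            lesions = {g: tuple(int(x) for x in v)
                       for g, v in dict(self.lesion_nodes).items()}
            for g, nodes in lesions.items():
                unknown = set(nodes) - labset
                if unknown:
                    raise ValueError(f"lesion nodes {sorted(unknown)} not in label set")
            object.__setattr__(self, "lesion_nodes", lesions)

    def labels(self) -> RoiLabelSet:
        if self.n_nodes == 26:
            return default_dmn_labels()
        return RoiLabelSet(tuple(range(1, self.n_nodes + 1)))

    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_attenuation)

    def attenuation(self, group: str) -> float:
        try:
            return float(self.group_attenuation[group])
        except KeyError:
            raise KeyError(f"group {group!r} not in generator config") from None

    def lesioned(self, group: str) -> tuple[int, ...]:
        if self.lesion_nodes is None:
            return ()
        return tuple(self.lesion_nodes.get(group, ()))


def _group_tag(group: str) -> int:
    return zlib.crc32(group.encode("utf-8")) & 0x7FFFFFFF


def _rng(config: GeneratorConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


def _lesion_mask(config: GeneratorConfig, group: str) -> np.ndarray:
    labels = config.labels().labels
    lesioned = set(config.lesioned(group))
    return np.array([lab in lesioned for lab in labels], dtype=bool)


# ---------------------------------------------------------------------------
# FC
# ---------------------------------------------------------------------------

def generate_fc_matrix(config: GeneratorConfig, group: str) -> ConnectivityMatrix:
    """Simulate node time series and return their Fisher-z correlation matrix.

    Node i's series is ``a * l_i . f(t) + eps_i(t)`` with shared factors f,
    loadings l_i drawn once per seed, group attenuation a, and i.i.d. Gaussian
    noise of sd ``noise_sd``; lesioned nodes have their loadings additionally
    halved.  The sample correlation matrix (positive semi-definite, unit
    diagonal) is Fisher-z transformed off the diagonal and the diagonal
    zeroed.  Deterministic given (seed, group).
    """
    a = config.attenuation(group)
    n, k, t = config.n_nodes, config.fc_latent_factors, config.n_timepoints
    if config.noise_sd == 0 and k == 1:
        warnings.warn(
            "noise_sd=0 with a single latent factor yields rank-1 series and "
            "degenerate (+/-1) correlations",
            RuntimeWarning,
            stacklevel=2,
        )
    loadings = _rng(config, _STREAM_FC_LOADINGS).normal(size=(n, k)) / np.sqrt(k)
    loadings = a * loadings
    lesion = _lesion_mask(config, group)
    loadings[lesion] *= 0.5

    rng = _rng(config, _STREAM_FC_NOISE, _group_tag(group))
    factors = rng.normal(size=(t, k))
    noise = rng.normal(scale=config.noise_sd, size=(t, n)) if config.noise_sd > 0 \
        else np.zeros((t, n))
    series = factors @ loadings.T + noise

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(series, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr = np.clip(corr, -1.0 + 1e-15, 1.0 - 1e-15)
    z = np.arctanh(corr)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z, config.labels(), "FC", group)


# ---------------------------------------------------------------------------
# SC
# ---------------------------------------------------------------------------

def _sc_base(config: GeneratorConfig) -> np.ndarray:
    """Seed-determined base weight matrix, shared by all groups."""
    n = config.n_nodes
    labels = config.labels().labels
    rng = _rng(config, _STREAM_SC_BASE)
    left = np.array([lab % 2 == 1 for lab in labels])
    same_hemi = np.equal.outer(left, left)
    p = np.where(
        same_hemi,
        min(config.intra_hemisphere_factor * config.sc_density, 1.0),
        config.sc_density,
    )
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < p[iu]
    weights = rng.gamma(config.sc_gamma_shape, config.sc_gamma_scale, len(iu[0]))
    w = np.zeros((n, n))
    w[iu] = np.where(present, weights, 0.0)
    w = w + w.T

    # repair: connect the positive-weight graph with a random spanning tree of
    # minimum-weight edges, so ATH and the Chow-Liu tree are well defined
    ncomp, comp = connected_components(csr_matrix(w > 0), directed=False)
    if ncomp > 1:
        repair = _rng(config, _STREAM_SC_REPAIR)
        wmin = float(w[w > 0].min()) if (w > 0).any() else 1.0
        order = repair.permutation(ncomp)
        merged = np.flatnonzero(comp == order[0]).tolist()
        for c in order[1:]:
            u = int(repair.choice(merged))
            v = int(repair.choice(np.flatnonzero(comp == c)))
            w[u, v] = w[v, u] = wmin
            merged.extend(np.flatnonzero(comp == c).tolist())
    return w


def generate_sc_matrix(config: GeneratorConfig, group: str) -> ConnectivityMatrix:
    """Sparse symmetric non-negative SC matrix for one group.

    The seed fixes topology and base weights; the group scales every weight
    by its attenuation and halves edges incident to its lesioned nodes.
    The positive-weight graph is guaranteed connected.  Deterministic given
    (seed, group).
    """
    a = config.attenuation(group)
    w = a * _sc_base(config)
    lesion = _lesion_mask(config, group)
    if lesion.any():
        incident = lesion[:, None] | lesion[None, :]
        w[incident] *= 0.5
    return ConnectivityMatrix(w, config.labels(), "SC", group)


def generate_study_set(config: GeneratorConfig) -> dict[tuple[str, str], ConnectivityMatrix]:
    """The six study inputs: {control, IDHmut, IDHwt} x {SC, FC}.

    Keyed by (group, modality); every matrix is regenerable in isolation by
    the corresponding single-matrix call with the same config.
    """
    out: dict[tuple[str, str], ConnectivityMatrix] = {}
    for group in config.groups():
        out[(group, "SC")] = generate_sc_matrix(config, group)
        out[(group, "FC")] = generate_fc_matrix(config, group)
    return out
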