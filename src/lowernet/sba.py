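"""Seed-based connectivity: spherical seeds, Fisher-z maps, seed selection.

For each of the 10 network nodes a 6 mm spherical seed yields a whole-brain
correlation map, Fisher z-transformed and thresholded at z > 0.55 (one-sided:
only positive connectivity survives).  Two seed placements are computed per
node -- the literature coordinate and a subject-specific coordinate on the
best-preserved grey matter nearby -- and the "less noisy and more specific"
map is kept, formalized here as two auditable scores:

* specificity = suprathreshold mass inside the network template / total
  suprathreshold mass (floor of one voxel),
* noise = fraction of suprathreshold voxels outside a dilated template.

Left- and right-seed maps are kept separate throughout; the voxelwise-max
fusion used by the group analysis lives in :func:`combine_left_right`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .networks import NetworkModel, NodeDef, sphere_mask
from .synthcohort import BoldRun

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_Z = 0.55
#: Fisher z is clipped here so r = 1 voxels stay finite
MAX_Z = float(np.arctanh(1.0 - 1e-7))


@dataclass
class ConnectivityMap:
    z_values: np.ndarray  # 3D, zeros below threshold
    seed_used: str  # node name
    placement: str  # "literature" | "subject_specific"
    threshold_z: float = DEFAULT_THRESHOLD_Z
    flags: list[str] = field(default_factory=list)
    specificity: float | None = None
    noise: float | None = None

    def __post_init__(self) -> None:
        nz = self.z_values[self.z_values != 0]
        if nz.size and (not np.all(np.isfinite(nz)) or np.any(nz <= self.threshold_z)):
            raise ValueError("stored non-zero z values must be finite and above threshold")


def extract_seed_timecourse(
    bold: np.ndarray,
    center: tuple[float, float, float],
    radius_voxels: float,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean time course over in-mask voxels within ``radius_voxels`` of center."""
    shape = bold.shape[:3]
    roi = sphere_mask(shape, center, radius_voxels)
    if brain_mask is not None:
        roi &= brain_mask
    if not roi.any():
        raise ValueError(f"seed sphere at {center} has no in-mask voxel")
    return bold[roi].mean(axis=0)


def seed_correlation_map(
    bold: np.ndarray,
    seed_series: np.ndarray,
    brain_mask: np.ndarray,
    threshold_z: float = DEFAULT_THRESHOLD_Z,
    seed_name: str = "seed",
    placement: str = "literature",
) -> ConnectivityMap:
    """Whole-brain Pearson correlation with the seed, Fisher-z thresholded.

    Voxels with z <= threshold are zeroed; zero-variance voxels get z = 0
    (their count is logged); a zero-variance seed is an error.  Perfect
    correlations are clipped to ``MAX_Z``.
    """
    seed = np.asarray(seed_series, dtype=np.float64)
    seed_c = seed - seed.mean()
    seed_norm = np.sqrt((seed_c**2).sum())
    if seed_norm == 0:
        raise ValueError(f"seed {seed_name!r} has zero variance")
    t = bold.shape[-1]
    y = np.asarray(bold[brain_mask], dtype=np.float64)  # v x t
    y_c = y - y.mean(axis=1, keepdims=True)
    y_norm = np.sqrt((y_c**2).sum(axis=1))
    dead = y_norm == 0
    if dead.any():
        logger.info("seed %s: %d zero-variance voxel(s) set to z=0", seed_name, int(dead.sum()))
    y_norm[dead] = 1.0
    r = (y_c @ seed_c) / (y_norm * seed_norm)
    r = np.clip(r, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -np.tanh(MAX_Z), np.tanh(MAX_Z)))
    z[dead] = 0.0
    z[z <= threshold_z] = 0.0
    zmap = np.zeros(bold.shape[:3])
    zmap[brain_mask] = z
    return ConnectivityMap(zmap, seed_used=seed_name, placement=placement, threshold_z=threshold_z)


def place_subject_seed(
    structural_volume: np.ndarray,
    gm_mask: np.ndarray,
    literature_center: tuple[float, float, float],
    search_radius_voxels: float = 3.0,
) -> tuple[tuple[int, int, int], bool]:
    """Subject-specific seed center: the in-GM voxel within the search radius
    of the literature coordinate with the highest structural intensity (the
    most preserved grey matter).  Ties break to the lowest linear index, so a
    fully intact neighbourhood returns the first-scanned maximal voxel.

    Returns ``(center, fallback_flag)``; if no GM voxel with positive
    intensity exists nearby the literature center is returned flagged.
    """
    shape = structural_volume.shape
    neigh = sphere_mask(shape, literature_center, search_radius_voxels) & gm_mask
    if not neigh.any():
        return tuple(int(round(c)) for c in literature_center), True
    vals = np.where(neigh, structural_volume, -np.inf)
    flat = np.argmax(vals)  # argmax returns the first (lowest linear index) max
    best = vals.flat[flat]
    if best <= 0:
        return tuple(int(round(c)) for c in literature_center), True
    # the literature center wins ties: scanning conceptually starts there
    lit = tuple(int(round(c)) for c in literature_center)
    if all(0 <= lit[i] < shape[i] for i in range(3)) and vals[lit] == best:
        return lit, False
    return tuple(int(i) for i in np.unravel_index(flat, shape)), False


def _map_scores(
    cmap: ConnectivityMap, network_template: np.ndarray, dilate_iters: int = 2
) -> tuple[float, float]:
    """(specificity, noise) scores used for dual-seed map selection."""
    z = cmap.z_values
    supra = z > 0
    total_mass = float(z[supra].sum())
    in_mass = float(z[supra & network_template].sum())
    specificity = in_mass / max(total_mass, 1.0)
    plausible = ndimage.binary_dilation(network_template, iterations=dilate_iters)
    n_supra = int(supra.sum())
    noise = float((supra & ~plausible).sum()) / max(n_supra, 1)
    return specificity, noise


def select_seed_map(
    map_literature: ConnectivityMap,
    map_subject: ConnectivityMap,
    network_template: np.ndarray,
) -> ConnectivityMap:
    """Choose the more specific of the two seed maps; ties break to lower
    noise, then to the literature placement.  Both scores are stored on the
    returned map so the choice can be audited."""
    if map_literature.z_values.shape != map_subject.z_values.shape:
        raise ValueError("maps must share a grid")
    spec_l, noise_l = _map_scores(map_literature, network_template)
    spec_s, noise_s = _map_scores(map_subject, network_template)
    map_literature.specificity, map_literature.noise = spec_l, noise_l
    map_subject.specificity, map_subject.noise = spec_s, noise_s
    if not map_literature.z_values.any() and not map_subject.z_values.any():
        map_literature.flags.append("empty")
        return map_literature
    if spec_s > spec_l:
        return map_subject
    if spec_s == spec_l and noise_s < noise_l:
        return map_subject
    return map_literature


def combine_left_right(map_l: np.ndarray, map_r: np.ndarray) -> np.ndarray:
    """Voxelwise maximum of the left-seed and right-seed maps."""
    if map_l.shape != map_r.shape:
        raise ValueError(f"shape mismatch: {map_l.shape} vs {map_r.shape}")
    return np.maximum(map_l, map_r)


def sba_subject(
    run: BoldRun,
    model: NetworkModel,
    structural: np.ndarray | None = None,
    threshold_z: float = DEFAULT_THRESHOLD_Z,
) -> dict[str, ConnectivityMap]:
    """All 10 node maps for one (preprocessed) subject.

    For every node the literature-seed and subject-seed maps are computed and
    the better one selected against the node's network template (the union of
    the network's node spheres).  When no structural volume is supplied only
    the literature placement is used.
    """
    shape = run.data.shape[:3]
    out: dict[str, ConnectivityMap] = {}
    for net, nodes in model.networks.items():
        template = model.network_mask(net, shape)
        for node in nodes:
            radius = model.radius_voxels(node)
            seed = extract_seed_timecourse(run.data, node.coordinate, radius, run.brain_mask)
            m_lit = seed_correlation_map(
                run.data, seed, run.brain_mask, threshold_z, node.name, "literature"
            )
            if structural is None:
                m_lit.specificity, m_lit.noise = _map_scores(m_lit, template)
                out[node.name] = m_lit
                continue
            center, fellback = place_subject_seed(structural, run.gm_mask, node.coordinate)
            seed2 = extract_seed_timecourse(run.data, center, radius, run.brain_mask)
            m_sub = seed_correlation_map(
                run.data, seed2, run.brain_mask, threshold_z, node.name, "subject_specific"
            )
            if fellback:
                m_sub.flags.append("no_preserved_gm")
            out[node.name] = select_seed_map(m_lit, m_sub, template)
    return out
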