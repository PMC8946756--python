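"""Spatial ICA, control-group network templates, and component vetting.

Per subject, the preprocessed BOLD run is decomposed into a fixed number of
30 spatial components (whitening + fixed-point unmixing on the voxels x time
matrix).  Group templates are built from temporally concatenated control
runs: for each network, the component most correlated with the network's
node-ROI mask is binarized at z >= 3.

Candidate components for a network are vetted on the three pieces of
information used in expert review, operationalized as thresholds:

* spatial specificity: suprathreshold (z >= 3) mass inside the template over
  mass outside it,
* power spectrum: fraction of time-course power below 0.1 Hz,
* time-series smoothness: lag-1 autocorrelation.

All vetting quantities are pure functions of (map, time course, template,
TR) and are reported whether or not a component is accepted, so a human
override (forced accept/reject) can be audited against them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

N_COMPONENTS = 30
TEMPLATE_Z = 3.0
COMPONENT_Z = 3.0


class IcaConvergenceError(RuntimeError):
    """Raised when fixed-point ICA fails to converge on two documented seeds."""


@dataclass
class ComponentSet:
    spatial_maps: np.ndarray  # (k, x, y, z), z-scored over brain mask
    time_courses: np.ndarray  # (k, t)
    brain_mask: np.ndarray
    n_components: int = N_COMPONENTS

    def __post_init__(self) -> None:
        if self.spatial_maps.shape[0] != self.n_components:
            raise ValueError("spatial_maps first axis must equal n_components")
        if not np.all(np.isfinite(self.time_courses)):
            raise ValueError("time courses must be finite")


@dataclass
class VettingThresholds:
    specificity_ratio: float = 1.0
    low_freq_fraction: float = 0.5
    smoothness: float = 0.3


@dataclass
class ComponentVetting:
    similarity: float
    specificity_ratio: float
    low_freq_fraction: float
    smoothness: float
    decision: str  # "accept" | "reject"


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------


def _spatial_ica(x: np.ndarray, n_components: int, seed: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """FastICA on a voxels x time matrix; returns (sources v x k, mixing t x k,
    converged)."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica = FastICA(
            n_components=n_components,
            algorithm="deflation",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=500,
            tol=1e-3,
            random_state=seed,
        )
        sources = ica.fit_transform(x)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return sources, ica.mixing_, converged


def run_subject_ica(
    bold: np.ndarray,
    brain_mask: np.ndarray,
    n_components: int = N_COMPONENTS,
    rng_seed: int = 0,
) -> ComponentSet:
    """Spatial ICA of one run with a fixed number of components.

    Maps are z-scored over the brain mask and sign-fixed so each map's
    skewness is positive (making the z >= 3 threshold comparable across
    components and subjects).  Deterministic given ``rng_seed``; on
    non-convergence a second documented seed (``rng_seed + 1000``) is tried
    before raising :class:`IcaConvergenceError`.
    """
    t = bold.shape[-1]
    if t <= n_components:
        raise ValueError(f"need more volumes ({t}) than components ({n_components})")
    x = np.asarray(bold[brain_mask], dtype=np.float64)  # v x t
    x = x - x.mean(axis=1, keepdims=True)
    sources = mixing = None
    for attempt, seed in enumerate((rng_seed, rng_seed + 1000)):
        sources, mixing, converged = _spatial_ica(x, n_components, seed)
        if converged:
            break
        logger.warning("ICA did not converge with seed %d (attempt %d)", seed, attempt + 1)
    else:
        raise IcaConvergenceError(
            f"ICA failed to converge with seeds {rng_seed} and {rng_seed + 1000}"
        )

    maps = np.zeros((n_components, *bold.shape[:3]))
    tcs = np.zeros((n_components, t))
    for k in range(n_components):
        m = sources[:, k]
        sd = m.std()
        m = (m - m.mean()) / (sd if sd > 0 else 1.0)
        sign = 1.0 if stats.skew(m) >= 0 else -1.0
        maps[k][brain_mask] = sign * m
        tcs[k] = sign * mixing[:, k]
    return ComponentSet(maps, tcs, brain_mask, n_components)


def build_group_templates(
    control_bolds: list[np.ndarray],
    brain_mask: np.ndarray,
    network_masks: dict[str, np.ndarray],
    n_components: int = N_COMPONENTS,
    z_thresh: float = TEMPLATE_Z,
    rng_seed: int = 0,
    min_similarity: float = 0.2,
) -> dict[str, np.ndarray]:
    """Network templates from temporally concatenated control runs.

    Group ICA = concatenate controls along time, decompose once; for each
    network, binarize (at z >= ``z_thresh``) the component whose map
    correlates best with the network's node-ROI mask.  A network whose best
    correlation is below ``min_similarity``, or whose template comes out
    empty, raises a ``ValueError`` naming the network.
    """
    if len(control_bolds) < 2:
        raise ValueError("need at least 2 control runs for group templates")
    concat = np.concatenate([b for b in control_bolds], axis=-1)
    cs = run_subject_ica(concat, brain_mask, n_components, rng_seed)
    templates: dict[str, np.ndarray] = {}
    for net, roi_mask in network_masks.items():
        sims = np.array(
            [template_similarity(cs.spatial_maps[k], roi_mask, brain_mask) for k in range(n_components)]
        )
        best = int(np.argmax(sims))
        if sims[best] < min_similarity:
            raise ValueError(
                f"no group component matches network {net} "
                f"(best correlation {sims[best]:.3f} < {min_similarity})"
            )
        tmpl = cs.spatial_maps[best] >= z_thresh
        if not tmpl.any():
            raise ValueError(f"template for network {net} is empty at z >= {z_thresh}")
        templates[net] = tmpl
    return templates


# ---------------------------------------------------------------------------
# Similarity and vetting
# ---------------------------------------------------------------------------


def template_similarity(
    component_map: np.ndarray, template: np.ndarray, brain_mask: np.ndarray
) -> float:
    """Pearson correlation between the component map and the binary template
    over the brain mask.  A constant component map yields 0 with a warning."""
    if component_map.shape != template.shape:
        raise ValueError("component map and template must share a grid")
    x = component_map[brain_mask].astype(float)
    y = template[brain_mask].astype(float)
    if x.std() == 0 or y.std() == 0:
        logger.warning("constant map or template in similarity computation; returning 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def low_frequency_fraction(time_course: np.ndarray, tr_seconds: float, cutoff_hz: float = 0.1) -> float:
    """Fraction of (non-DC) spectral power below ``cutoff_hz``."""
    tc = np.asarray(time_course, dtype=float)
    tc = tc - tc.mean()
    power = np.abs(np.fft.rfft(tc)) ** 2
    freqs = np.fft.rfftfreq(len(tc), d=tr_seconds)
    total = power[1:].sum()
    if total == 0:
        return 0.0
    return float(power[(freqs > 0) & (freqs < cutoff_hz)].sum() / total)


def lag1_autocorrelation(time_course: np.ndarray) -> float:
    tc = np.asarray(time_course, dtype=float)
    tc = tc - tc.mean()
    denom = (tc**2).sum()
    if denom == 0:
        return 0.0
    return float((tc[:-1] * tc[1:]).sum() / denom)


def vet_component(
    component_map: np.ndarray,
    time_course: np.ndarray,
    template: np.ndarray,
    brain_mask: np.ndarray,
    tr_seconds: float,
    thresholds: VettingThresholds | None = None,
) -> ComponentVetting:
    """Three-criterion vetting: spatial specificity to the template, low-
    frequency power, and time-course smoothness.  Accept requires all three.
    """
    th = thresholds or VettingThresholds()
    supra = component_map >= COMPONENT_Z
    in_mass = float(component_map[supra & template].sum())
    out_mass = float(component_map[supra & ~template].sum())
    if in_mass == 0.0:
        ratio = 0.0
    elif out_mass == 0.0:
        ratio = np.inf
    else:
        ratio = in_mass / out_mass
    lff = low_frequency_fraction(time_course, tr_seconds)
    smooth = lag1_autocorrelation(time_course)
    sim = template_similarity(component_map, template, brain_mask)
    accept = ratio >= th.specificity_ratio and lff >= th.low_freq_fraction and smooth >= th.smoothness
    return ComponentVetting(
        similarity=sim,
        specificity_ratio=float(ratio),
        low_freq_fraction=lff,
        smoothness=smooth,
        decision="accept" if accept else "reject",
    )


def pick_network_component(
    components: ComponentSet,
    template: np.ndarray,
    tr_seconds: float,
    thresholds: VettingThresholds | None = None,
    overrides: dict[int, str] | None = None,
) -> tuple[int, ComponentVetting] | None:
    """Highest-similarity component that passes vetting, or ``None``.

    Components are ranked by template similarity (ties break to the lower
    component index); the first accepted one is returned as
    ``(component_index, vetting)``.  ``overrides`` maps component index to
    a forced "accept" or "reject" (the human-review escape hatch); forced
    decisions replace the automated one but the vetting quantities are still
    computed and reported.
    """
    overrides = overrides or {}
    sims = np.array(
        [
            template_similarity(components.spatial_maps[k], template, components.brain_mask)
            for k in range(components.n_components)
        ]
    )
    order = np.argsort(-sims, kind="stable")
    for k in order:
        vet = vet_component(
            components.spatial_maps[k],
            components.time_courses[k],
            template,
            components.brain_mask,
            tr_seconds,
            thresholds,
        )
        forced = overrides.get(int(k))
        if forced is not None:
            if forced not in ("accept", "reject"):
                raise ValueError(f"override for component {k} must be accept/reject")
            vet = ComponentVetting(
                vet.similarity, vet.specificity_ratio, vet.low_freq_fraction,
                vet.smoothness, forced,
            )
        if vet.decision == "accept":
            return int(k), vet
    return None
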