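"""Synthetic cohort generator: BOLD runs, structural damage and clinical scores.

The generator emulates the statistical structure the downstream analysis
assumes for a chronic disorders-of-consciousness (DoC) cohort:

* one ~9.5 min resting-state run per subject (200 volumes at TR 2.8 s),
* four lower-order networks (SM, AUD, LVIS, MVIS) whose 10 bilateral nodes
  share band-limited (0.01-0.08 Hz) latent signals,
* within-network coupling graded by diagnosis (VS/UWS < MCS < SD < control),
* etiology-dependent focal lesions that attenuate a node's coupling *and*
  lower its structural MRI rating (this covariation is what the combined
  fMRI+MRI classification models exploit),
* head-motion traces with occasional large spikes, plus matching artifact
  frames in the BOLD data, to exercise scrubbing,
* CRS-R behavioural scores drawn so that the total score increases
  stochastically with a subject's mean residual coupling, with the visual
  subscale spread over its full 0-5 range and the motor/auditory subscales
  polarized on one or two values.

Everything is reproducible bit-for-bit from ``CohortSpec.rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import NETWORK_NAMES, NetworkModel, default_synthetic_model

PATIENT_GROUPS = ("VS/UWS", "MCS", "SD")
DIAGNOSES = PATIENT_GROUPS + ("control",)
ETIOLOGIES = ("traumatic", "vascular", "anoxic")

#: CRS-R subscale admissible ranges
SUBSCALE_RANGE = {"motor": (0, 6), "auditory": (0, 4), "visual": (0, 5)}


# ---------------------------------------------------------------------------
# Specification and record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults define the reference study conditions used throughout the test
    suite: group coupling 0.2 / 0.5 / 0.8 for VS/UWS / MCS / SD, an etiology
    mix close to one third each, a 32x32x24 grid of 3 mm voxels and
    200 volumes at TR 2.8 s.
    """

    n_vs: int = 20
    n_mcs: int = 20
    n_sd: int = 10
    n_controls: int = 6
    etiology_mix: tuple[float, float, float] = (0.34, 0.33, 0.33)
    coupling_by_group: dict[str, float] = field(
        default_factory=lambda: {"VS/UWS": 0.2, "MCS": 0.5, "SD": 0.8, "control": 0.85}
    )
    lesion_prob_by_etiology: dict[str, float] = field(
        default_factory=lambda: {"traumatic": 0.25, "vascular": 0.35, "anoxic": 0.30, "none": 0.0}
    )
    #: structural damage scales with clinical severity: without this gradient
    #: the structural-rating classification model would carry no signal
    lesion_severity_by_group: dict[str, float] = field(
        default_factory=lambda: {"VS/UWS": 1.4, "MCS": 1.0, "SD": 0.5, "control": 0.0}
    )
    noise_sd: float = 1.0
    n_artifact_sources: int = 30
    artifact_amplitude: float = 1.0
    drift_amplitude: float = 0.5
    spike_prob: float = 0.02
    spike_magnitude_mm: float = 3.0
    grid_shape: tuple[int, int, int] = (32, 32, 24)
    voxel_size_mm: float = 3.0
    n_volumes: int = 200
    tr_seconds: float = 2.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_vs, self.n_mcs, self.n_sd, self.n_controls) < 0:
            raise ValueError("group counts must be >= 0")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isclose(sum(self.etiology_mix), 1.0):
            raise ValueError("etiology_mix must sum to 1")
        c = self.coupling_by_group
        for g in DIAGNOSES:
            if g not in c:
                raise ValueError(f"coupling_by_group missing {g!r}")
            if not 0.0 <= c[g] <= 1.0:
                raise ValueError("coupling must lie in [0, 1]")
        if not c["VS/UWS"] <= c["MCS"] <= c["SD"]:
            raise ValueError("coupling must be non-decreasing over VS/UWS -> MCS -> SD")
        for p in list(self.lesion_prob_by_etiology.values()) + [self.spike_prob]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_patients(self) -> int:
        return self.n_vs + self.n_mcs + self.n_sd

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls


@dataclass
class SubjectRecord:
    """Per-subject clinical, demographic and ground-truth information."""

    subject_id: str
    diagnosis: str
    etiology: str
    age_years: int
    disease_duration_months: float
    crs_r_total: int
    crs_r_modified: int
    subscale_scores: dict[str, int]
    mri_node_ratings: dict[str, float]
    ground_truth_presence: dict[str, bool]
    node_effective_coupling: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        for name, (lo, hi) in SUBSCALE_RANGE.items():
            v = self.subscale_scores.get(name)
            if v is None or not lo <= v <= hi:
                raise ValueError(f"subscale {name} out of range: {v}")
        for node, r in self.mri_node_ratings.items():
            if not 0.0 <= r <= 4.0:
                raise ValueError(f"MRI rating for {node} outside 0-4: {r}")
        for net in NETWORK_NAMES:
            if net not in self.ground_truth_presence:
                raise ValueError(f"ground_truth_presence missing {net}")


@dataclass
class BoldRun:
    """One subject's 4D BOLD series plus masks and motion parameters."""

    data: np.ndarray  # (x, y, z, t)
    tr_seconds: float
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    motion_params: np.ndarray  # (t, 6): 3 translations (mm), 3 rotations (rad)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D")
        shape = self.data.shape[:3]
        for m in (self.brain_mask, self.gm_mask, self.wm_mask, self.csf_mask):
            if m.shape != shape:
                raise ValueError("mask shape must match BOLD spatial shape")
        if self.motion_params.shape != (self.data.shape[3], 6):
            raise ValueError("motion_params must be t x 6")
        if np.any(self.gm_mask & self.wm_mask) or np.any(self.gm_mask & self.csf_mask) or np.any(
            self.wm_mask & self.csf_mask
        ):
            raise ValueError("GM/WM/CSF masks must be mutually exclusive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


# ---------------------------------------------------------------------------
# Geometry: synthetic brain and tissue masks
# ---------------------------------------------------------------------------


def synthetic_masks(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Ellipsoidal brain with a central WM core and a small CSF ventricle.

    GM is the brain shell outside WM and CSF; the three tissue masks are
    mutually exclusive by construction.
    """
    nx, ny, nz = shape
    center = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)

    def ellipsoid(semi: tuple[float, float, float]) -> np.ndarray:
        x, y, z = np.ogrid[:nx, :ny, :nz]
        return (
            ((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2
        ) <= 1.0

    brain = ellipsoid((nx * 0.47, ny * 0.47, nz * 0.46))
    wm_core = ellipsoid((nx * 0.22, ny * 0.22, nz * 0.22))
    csf = ellipsoid((nx * 0.08, ny * 0.08, nz * 0.08))
    wm = wm_core & ~csf & brain
    csf = csf & brain
    gm = brain & ~wm & ~csf
    return {"brain": brain, "gm": gm, "wm": wm, "csf": csf}


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------


def bandlimited_signal(
    n_volumes: int,
    tr_seconds: float,
    rng: np.random.Generator,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> np.ndarray:
    """Unit-variance Gaussian signal with power confined to [low_hz, high_hz].

    Built by filling only the in-band rFFT bins with complex Gaussian noise,
    so the band-pass preprocessing stage preserves the signal by design.
    """
    freqs = np.fft.rfftfreq(n_volumes, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():  # degenerate very-short series
        keep = np.zeros_like(freqs, dtype=bool)
        keep[1] = True
    spec = np.zeros(len(freqs), dtype=complex)
    n_keep = int(keep.sum())
    spec[keep] = rng.standard_normal(n_keep) + 1j * rng.standard_normal(n_keep)
    sig = np.fft.irfft(spec, n=n_volumes)
    sig -= sig.mean()
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def embed_network_signal(
    volume_shape: tuple[int, int, int],
    node_rois: list[np.ndarray],
    latent_series: np.ndarray,
    coupling: float | list[float],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Embed a shared latent signal into disjoint node ROIs of a noise volume.

    Each voxel series inside node ``i`` is
    ``c_i * latent + sqrt(1 - c_i**2) * noise_sd * eps`` with independent
    standard-normal ``eps``; background voxels are pure ``noise_sd * eps``.
    With ``noise_sd = 1`` the voxel-latent correlation is exactly ``c_i`` in
    expectation.
    """
    t = len(latent_series)
    couplings = np.broadcast_to(np.asarray(coupling, dtype=float), (len(node_rois),))
    if np.any((couplings < 0) | (couplings > 1)):
        raise ValueError("coupling must lie in [0, 1]")
    occupancy = np.zeros(volume_shape, dtype=int)
    for roi in node_rois:
        if roi.shape != volume_shape:
            raise ValueError("node ROI shape must match volume shape")
        occupancy += roi.astype(int)
    if occupancy.max() > 1:
        raise ValueError("node ROIs must be disjoint")

    data = rng.standard_normal((*volume_shape, t)) * noise_sd
    for roi, c in zip(node_rois, couplings):
        n_vox = int(roi.sum())
        if n_vox == 0:
            continue
        eps = rng.standard_normal((n_vox, t))
        data[roi] = c * latent_series + np.sqrt(1.0 - c**2) * noise_sd * eps
    return data


def simulate_motion(
    n_volumes: int,
    spike_prob: float,
    spike_magnitude_mm: float,
    rng: np.random.Generator,
    drift_sd_mm: float = 0.02,
    drift_sd_rad: float = 0.0002,
) -> tuple[np.ndarray, np.ndarray]:
    """Motion parameters (t x 6) with a slow random-walk drift plus spikes.

    Returns ``(params, spike_frames)`` where ``spike_frames`` is the sorted
    array of frames at which a translation jump of ``spike_magnitude_mm``
    was injected (the ground truth for scrubbing tests).  A spike at frame k
    is a one-frame x-translation excursion, so the Power framewise
    displacement at frame k is at least ``spike_magnitude_mm``.
    """
    if spike_prob > 0 and spike_magnitude_mm <= 2.0:
        raise ValueError("spike_magnitude_mm must exceed 2 mm so spikes are scrubbable")
    steps = np.column_stack(
        [
            rng.standard_normal((n_volumes, 3)) * drift_sd_mm,
            rng.standard_normal((n_volumes, 3)) * drift_sd_rad,
        ]
    )
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    spike_frames = np.flatnonzero(rng.random(n_volumes) < spike_prob)
    spike_frames = spike_frames[spike_frames > 0]  # frame 0 has FD defined as 0
    for k in spike_frames:
        params[k, 0] += spike_magnitude_mm * (1 if rng.random() < 0.5 else -1)
    return params, spike_frames


# ---------------------------------------------------------------------------
# Clinical score model
# ---------------------------------------------------------------------------


def _clip_int(x: float, lo: int, hi: int) -> int:
    return int(np.clip(round(x), lo, hi))


def _draw_clinical(
    diagnosis: str,
    mean_coupling: float,
    visual_coupling: float,
    auditory_coupling: float,
    rng: np.random.Generator,
) -> dict:
    """CRS-R scores tied stochastically to residual coupling.

    The total score rises with mean coupling (slope 20 over the [0,1]
    coupling range, roughly spanning the 0-23 CRS-R range); the visual
    subscale uses its full 0-5 range in proportion to visual-network
    coupling, while motor and auditory scores are concentrated on one or two
    values, mirroring the score polarization seen clinically in chronic DoC.
    """
    total = _clip_int(2.0 + 20.0 * mean_coupling + rng.normal(0, 1.5), 0, 23)
    modified = _clip_int(0.8 * total + rng.normal(0, 1.0), 0, 20)
    visual = _clip_int(5.0 * visual_coupling + rng.normal(0, 0.7), 0, 5)
    # motor: mass on 2; SD subjects occasionally reach 3-6
    if diagnosis == "SD" and rng.random() < 0.6:
        motor = _clip_int(rng.integers(3, 7), 0, 6)
    else:
        motor = 1 if rng.random() < 0.15 else 2
    # auditory: mass on 1-2 with a weak coupling link
    p2 = 0.2 + 0.5 * auditory_coupling
    auditory = _clip_int(1 + (rng.random() < p2) + (rng.random() < 0.08), 0, 4)
    return {
        "crs_r_total": total,
        "crs_r_modified": modified,
        "subscales": {"motor": motor, "auditory": auditory, "visual": visual},
    }


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: ground-truth presence: coupling a node must retain to count as functional
GT_NODE_COUPLING = 0.35


def _presence_from_coupling(model: NetworkModel, eff: dict[str, float]) -> dict[str, bool]:
    out = {}
    for net in NETWORK_NAMES:
        good = sum(eff[nd.name] >= GT_NODE_COUPLING for nd in model.nodes(net))
        out[net] = good >= (2 if net == "SM" else 1)
    return out


def _draw_subject_biology(
    spec: CohortSpec,
    model: NetworkModel,
    subject_id: str,
    diagnosis: str,
    etiology: str,
    rng: np.random.Generator,
) -> tuple[SubjectRecord, np.ndarray, dict[str, float]]:
    """Lesions, structural map and clinical scores for one subject (no BOLD)."""
    masks = synthetic_masks(spec.grid_shape)
    base_coupling = spec.coupling_by_group[diagnosis]
    lesion_p = spec.lesion_prob_by_etiology.get(etiology, 0.0) * spec.lesion_severity_by_group.get(
        diagnosis, 1.0
    )
    lesion_p = min(lesion_p, 1.0)

    # lesions: per-node attenuation of coupling, mirrored in the MRI rating
    eff: dict[str, float] = {}
    mri: dict[str, float] = {}
    structural = masks["gm"].astype(np.float32)
    for node in model.nodes():
        if rng.random() < lesion_p:
            atten = rng.uniform(0.0, 0.3)
            rating = _clip_int(4.0 * atten + rng.normal(0, 0.4), 0, 2)
            roi = model.node_roi(node, spec.grid_shape)
            structural[roi] *= atten
        else:
            atten = 1.0
            rating = 4 if rng.random() < 0.7 else 3
        eff[node.name] = base_coupling * atten
        mri[node.name] = float(rating)

    # clinical scores tied to residual coupling
    mean_c = float(np.mean(list(eff.values())))
    vis_nodes = [nd.name for nd in model.nodes("LVIS")] + [nd.name for nd in model.nodes("MVIS")]
    vis_c = float(np.mean([eff[n] for n in vis_nodes]))
    aud_c = float(np.mean([eff[nd.name] for nd in model.nodes("AUD")]))
    clin = _draw_clinical(diagnosis, mean_c, vis_c, aud_c, rng)

    if diagnosis == "control":
        age = int(rng.integers(17, 67))
        duration = 0.0
    else:
        age = int(rng.integers(19, 84))
        duration = float(np.clip(np.exp(rng.normal(np.log(27.0), 0.8)), 2.0, 252.0))

    record = SubjectRecord(
        subject_id=subject_id,
        diagnosis=diagnosis,
        etiology=etiology,
        age_years=age,
        disease_duration_months=round(duration, 1),
        crs_r_total=clin["crs_r_total"],
        crs_r_modified=clin["crs_r_modified"],
        subscale_scores=clin["subscales"],
        mri_node_ratings=mri,
        ground_truth_presence=_presence_from_coupling(model, eff),
        node_effective_coupling=eff,
    )
    return record, structural, eff


def generate_subject(
    spec: CohortSpec,
    model: NetworkModel,
    subject_id: str,
    diagnosis: str,
    etiology: str,
    seed_seq: np.random.SeedSequence,
    with_bold: bool = True,
) -> tuple[SubjectRecord, BoldRun | None, np.ndarray]:
    """Generate one subject: record, BOLD run and structural (damage) map.

    The clinical/lesion draws and the BOLD synthesis use separate child
    streams of ``seed_seq``, so records are identical whether or not the
    (much heavier) BOLD volume is generated.
    """
    seq_bio, seq_bold = seed_seq.spawn(2)
    record, structural, eff = _draw_subject_biology(
        spec, model, subject_id, diagnosis, etiology, np.random.default_rng(seq_bio)
    )
    if not with_bold:
        return record, None, structural
    rng = np.random.default_rng(seq_bold)
    masks = synthetic_masks(spec.grid_shape)

    # BOLD: network latents embedded in node ROIs over background noise
    node_list = list(model.nodes())
    rois = [model.node_roi(nd, spec.grid_shape) for nd in node_list]
    couplings = [eff[nd.name] for nd in node_list]
    latents = {
        net: bandlimited_signal(spec.n_volumes, spec.tr_seconds, rng) for net in NETWORK_NAMES
    }
    data = rng.standard_normal((*spec.grid_shape, spec.n_volumes), dtype=np.float32)
    data *= spec.noise_sd
    for node, roi, c in zip(node_list, rois, couplings):
        net = node.name.split("_")[0]
        n_vox = int(roi.sum())
        eps = rng.standard_normal((n_vox, spec.n_volumes))
        series = c * latents[net] + np.sqrt(1.0 - c**2) * spec.noise_sd * eps
        data[roi] = series.astype(np.float32)

    # structured physiological/vascular noise: focal smooth blobs (vessel /
    # CSF-edge / rim-like sources) with broadband time courses.  These
    # compete with the neural networks for the fixed number of ICA
    # components, as vascular and physiological sources do in real
    # resting-state data -- the mechanism component vetting exists to handle.
    brain_idx = np.argwhere(masks["brain"])
    for _ in range(spec.n_artifact_sources):
        cx, cy, cz = brain_idx[rng.integers(len(brain_idx))]
        sig = rng.uniform(1.5, 3.0)
        x, y, z = np.ogrid[: spec.grid_shape[0], : spec.grid_shape[1], : spec.grid_shape[2]]
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        smap = np.exp(-0.5 * d2 / sig**2)
        smap[d2 > (3 * sig) ** 2] = 0.0
        smap[~masks["brain"]] = 0.0
        amp = rng.uniform(0.8, 2.0) * spec.artifact_amplitude * spec.noise_sd
        tc = rng.standard_normal(spec.n_volumes)
        data += (amp * smap[..., None] * tc).astype(np.float32)

    # physiological nuisance: WM and CSF compartment signals plus linear trend
    t_axis = np.linspace(-1, 1, spec.n_volumes, dtype=np.float32)
    wm_sig = bandlimited_signal(spec.n_volumes, spec.tr_seconds, rng, 0.0, 0.03)
    csf_sig = bandlimited_signal(spec.n_volumes, spec.tr_seconds, rng, 0.0, 0.05)
    data[masks["wm"]] += (0.6 * spec.noise_sd) * wm_sig.astype(np.float32)
    data[masks["csf"]] += (0.6 * spec.noise_sd) * csf_sig.astype(np.float32)
    data[masks["brain"]] += (spec.drift_amplitude * spec.noise_sd) * t_axis

    # motion: drift + spikes, with matching global artifact frames in the data
    motion, spike_frames = simulate_motion(
        spec.n_volumes, spec.spike_prob, spec.spike_magnitude_mm, rng
    )
    for k in spike_frames:
        artifact = rng.standard_normal(int(masks["brain"].sum())).astype(np.float32)
        data[masks["brain"], k] += 4.0 * spec.noise_sd * artifact

    run = BoldRun(
        data=data,
        tr_seconds=spec.tr_seconds,
        brain_mask=masks["brain"],
        gm_mask=masks["gm"],
        wm_mask=masks["wm"],
        csf_mask=masks["csf"],
        motion_params=motion,
    )
    return record, run, structural


def generate_cohort(
    spec: CohortSpec,
    model: NetworkModel | None = None,
    with_bold: bool = True,
) -> tuple[list[SubjectRecord], list[BoldRun | None], list[np.ndarray]]:
    """Generate the full cohort (patients then controls), reproducibly.

    Returns parallel lists of subject records, BOLD runs and structural
    (lesion-attenuated GM) maps.  Etiologies are assigned by cycling through
    the etiology mix deterministically within each diagnostic group so that
    stratum sizes are as close to ``etiology_mix`` as rounding allows.
    ``with_bold=False`` skips BOLD synthesis (runs come back as ``None``);
    records are identical either way.
    """
    if model is None:
        model = default_synthetic_model(spec.voxel_size_mm)
    root = np.random.SeedSequence(spec.rng_seed)
    groups = (
        [("VS/UWS", spec.n_vs), ("MCS", spec.n_mcs), ("SD", spec.n_sd), ("control", spec.n_controls)]
    )
    n_total = spec.n_subjects
    seqs = root.spawn(n_total)

    records: list[SubjectRecord] = []
    runs: list[BoldRun] = []
    structurals: list[np.ndarray] = []
    idx = 0
    for diagnosis, count in groups:
        # deterministic largest-remainder assignment of etiologies
        if diagnosis == "control":
            etis = ["none"] * count
        else:
            quotas = [count * p for p in spec.etiology_mix]
            base = [int(q) for q in quotas]
            rem = count - sum(base)
            order = np.argsort([b - q for b, q in zip(base, quotas)])
            for j in range(rem):
                base[order[j]] += 1
            etis = [e for e, b in zip(ETIOLOGIES, base) for _ in range(b)]
        for j in range(count):
            sid = f"sub-{idx + 1:03d}"
            rec, run, struct = generate_subject(
                spec, model, sid, diagnosis, etis[j], seqs[idx], with_bold=with_bold
            )
            records.append(rec)
            runs.append(run)
            structurals.append(struct)
            idx += 1
    return records, runs, structurals


# ---------------------------------------------------------------------------
# On-disk representation
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject_id",
    "diagnosis",
    "etiology",
    "age_years",
    "disease_duration_months",
    "crs_r_total",
    "crs_r_modified",
    "crs_r_motor",
    "crs_r_auditory",
    "crs_r_visual",
]


def records_to_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Cohort table (one row per subject) with MRI node ratings as columns."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "diagnosis": r.diagnosis,
            "etiology": r.etiology,
            "age_years": r.age_years,
            "disease_duration_months": r.disease_duration_months,
            "crs_r_total": r.crs_r_total,
            "crs_r_modified": r.crs_r_modified,
            "crs_r_motor": r.subscale_scores["motor"],
            "crs_r_auditory": r.subscale_scores["auditory"],
            "crs_r_visual": r.subscale_scores["visual"],
        }
        for node, v in r.mri_node_ratings.items():
            row[f"mri_{node}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    out_dir: str | Path,
    records: list[SubjectRecord],
    runs: list[BoldRun],
    structurals: list[np.ndarray],
    model: NetworkModel,
    voxel_size_mm: float = 3.0,
) -> None:
    """Write BOLD + masks as NIfTI-1, the cohort table as TSV, ground truth as JSON."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    records_to_table(records).to_csv(out / "cohort.tsv", sep="\t", index=False)
    model.save(out / "networks.yaml")
    gt = {
        r.subject_id: {
            "ground_truth_presence": r.ground_truth_presence,
            "node_effective_coupling": r.node_effective_coupling,
        }
        for r in records
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2))
    for rec, run, struct in zip(records, runs, structurals):
        sdir = out / rec.subject_id
        sdir.mkdir(exist_ok=True)
        nib.save(nib.Nifti1Image(run.data, affine), sdir / "bold.nii.gz")
        nib.save(nib.Nifti1Image(struct, affine[:4, :4]), sdir / "structural.nii.gz")
        for name in ("brain", "gm", "wm", "csf"):
            m = getattr(run, f"{name}_mask").astype(np.uint8)
            nib.save(nib.Nifti1Image(m, affine), sdir / f"mask_{name}.nii.gz")
        np.savetxt(sdir / "motion.par", run.motion_params, fmt="%.6f")
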