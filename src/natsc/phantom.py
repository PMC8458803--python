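"""Digital phantoms and synthetic multi-echo sodium acquisitions.

This module generates the ground-truth side of the pipeline: a labeled volume
whose compartments (deep gray nuclei, cortical gray matter shell, white matter,
CSF, and six external reference tubes) carry known total sodium concentrations
(TSC, mmol/L wet tissue) and bi-exponential relaxation parameters; a simulated
multi-echo acquisition of that phantom (24 echo times from 0.20 to 70.78 ms by
default, optional Gaussian blur, Rician noise); and sampled per-subject cohort
ground truths for a two-group study (default 10 iPD patients vs 12 healthy
controls, with group means and SDs as reported for early-stage idiopathic
Parkinson's disease at 7 T).

Geometry is parametric (spheres, ellipsoids, a cortical shell) on a small
isotropic grid — a stand-in for segmented anatomy that keeps desk-scale
runtimes while preserving the quantification problem: signal proportional to
TSC, bi-exponential decay, tubes outside the intracranial volume (ICV) but
inside the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .relaxometry import biexp_signal

__all__ = [
    "ROI_NAMES",
    "EchoSchedule",
    "default_echo_schedule",
    "Geometry",
    "CompartmentSpec",
    "PhantomSpec",
    "LabeledPhantom",
    "MultiEchoImage",
    "CohortGroundTruth",
    "default_phantom_spec",
    "build_phantom",
    "simulate_multiecho",
    "sample_cohort",
    "default_group_params",
    "default_volume_params",
]

#: The six regions of interest quantified by the pipeline.
ROI_NAMES = ("SN", "putamen", "caudate", "pallidum", "thalamus", "cortical_gm")

# The three interleaved 8-echo acquisitions (ms).  Running the sequence three
# times with shifted echo trains yields 24 echo times spanning 0.20-70.78 ms.
ECHO_TRAIN_1 = (0.20, 9.70, 19.20, 28.70, 38.20, 47.70, 57.20, 66.70)
ECHO_TRAIN_2 = (1.56, 11.06, 20.56, 30.06, 39.56, 49.06, 58.56, 68.06)
ECHO_TRAIN_3 = (4.28, 13.78, 23.28, 32.78, 42.28, 51.78, 61.28, 70.78)

# Group-level TSC mean/SD (mmol/L wet tissue) per ROI for early iPD patients
# and age-matched healthy controls — the cohort generator's default parameters.
_IPD_TSC = {
    "SN": (43.73, 4.64),
    "putamen": (48.65, 4.58),
    "caudate": (54.22, 4.36),
    "pallidum": (45.80, 4.19),
    "thalamus": (50.60, 5.92),
    "cortical_gm": (56.34, 3.92),
}
_HC_TSC = {
    "SN": (37.72, 5.62),
    "putamen": (43.66, 5.04),
    "caudate": (52.35, 5.50),
    "pallidum": (41.07, 4.94),
    "thalamus": (46.29, 5.14),
    "cortical_gm": (50.81, 5.50),
}

# Normalized ROI volumes (% of intracranial volume), mean/SD per group.
_IPD_NVOL = {
    "SN": (0.07, 0.01),
    "putamen": (0.62, 0.14),
    "caudate": (0.48, 0.07),
    "pallidum": (0.23, 0.03),
    "thalamus": (0.97, 0.14),
    "cortical_gm": (42.53, 5.67),
}
_HC_NVOL = {
    "SN": (0.08, 0.01),
    "putamen": (0.69, 0.11),
    "caudate": (0.50, 0.07),
    "pallidum": (0.24, 0.04),
    "thalamus": (1.01, 0.15),
    "cortical_gm": (43.37, 4.98),
}

#: Default tissue relaxation parameters (ms, ms, unitless).  Plausible
#: bi-exponential regime for the 0.20-70.78 ms window; generator inputs,
#: not physiological claims.
DEFAULT_T2_SHORT = 4.0
DEFAULT_T2_LONG = 35.0
DEFAULT_SHORT_FRACTION = 0.6

#: Default reference-tube concentrations (mmol/L): six equally spaced values
#: spanning the 25-100 mmol/L calibration range.
DEFAULT_TUBE_CONCENTRATIONS = (25.0, 40.0, 55.0, 70.0, 85.0, 100.0)

#: Ground-truth TSC for compartments outside the six graded ROIs.
DEFAULT_WM_TSC = 35.0
DEFAULT_CSF_TSC = 140.0


def default_group_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group (mean, sd) TSC parameters for each ROI."""
    return {"iPD": dict(_IPD_TSC), "HC": dict(_HC_TSC)}


def default_volume_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group (mean, sd) normalized-volume parameters (% of ICV)."""
    return {"iPD": dict(_IPD_NVOL), "HC": dict(_HC_NVOL)}


@dataclass(frozen=True)
class EchoSchedule:
    """Ordered echo times (ms) sampling the decay curve."""

    te_values: tuple[float, ...]

    def __post_init__(self):
        te = np.asarray(self.te_values, dtype=float)
        if te.size == 0:
            raise ValueError("echo schedule is empty")
        if np.any(te <= 0):
            raise ValueError("all echo times must be > 0")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "te_values", tuple(float(t) for t in te))

    def __len__(self):
        return len(self.te_values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.te_values, dtype=float)


def default_echo_schedule() -> EchoSchedule:
    """The default 24-echo schedule: sorted merge of the three 8-echo trains.

    Spans 0.20 to 70.78 ms; merging is order-invariant.
    """
    return EchoSchedule(tuple(sorted(ECHO_TRAIN_1 + ECHO_TRAIN_2 + ECHO_TRAIN_3)))


@dataclass(frozen=True)
class Geometry:
    """Parametric shape in voxel coordinates.

    kinds:
      - ``sphere``: ``center`` (3,), ``radii`` scalar or (3,)
      - ``ellipsoid``: ``center`` (3,), ``radii`` (3,)
      - ``shell``: spherical shell, ``radii = (r_inner, r_outer)``, voxels with
        r_inner < r <= r_outer
      - ``fill_sphere``: all voxels within ``radii`` (scalar) of ``center`` not
        claimed by any explicitly shaped compartment (rendered last; exempt
        from the overlap check by construction)
    """

    kind: str
    center: tuple[float, float, float]
    radii: tuple[float, ...]

    def mask(self, grid_shape, claimed=None) -> np.ndarray:
        zyx = np.indices(grid_shape, dtype=float)
        d = [zyx[i] - self.center[i] for i in range(3)]
        if self.kind == "sphere":
            r = self.radii[0] if len(self.radii) == 1 else None
            if r is not None:
                m = d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= r**2
            else:
                m = sum((d[i] / self.radii[i]) ** 2 for i in range(3)) <= 1.0
        elif self.kind == "ellipsoid":
            m = sum((d[i] / self.radii[i]) ** 2 for i in range(3)) <= 1.0
        elif self.kind == "shell":
            r2 = d[0] ** 2 + d[1] ** 2 + d[2] ** 2
            m = (r2 > self.radii[0] ** 2) & (r2 <= self.radii[1] ** 2)
        elif self.kind == "fill_sphere":
            m = d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= self.radii[0] ** 2
            if claimed is not None:
                m &= ~claimed
        else:
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        return m


@dataclass(frozen=True)
class CompartmentSpec:
    """One homogeneous compartment: label, ground truth, relaxation, shape."""

    label_id: int
    name: str
    true_tsc: float
    geometry: Geometry
    t2_short: float = DEFAULT_T2_SHORT
    t2_long: float = DEFAULT_T2_LONG
    short_fraction: float = DEFAULT_SHORT_FRACTION
    is_tube: bool = False

    def __post_init__(self):
        if self.label_id <= 0:
            raise ValueError("label_id must be positive (0 is background)")
        if self.true_tsc < 0:
            raise ValueError("true_tsc must be >= 0")
        if self.t2_short > self.t2_long:
            raise ValueError("t2_short must not exceed t2_long")
        if not (0.0 <= self.short_fraction <= 1.0):
            raise ValueError("short_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: grid, voxel size, compartments, ICV labels."""

    grid_shape: tuple[int, int, int]
    voxel_size: float
    compartments: tuple[CompartmentSpec, ...]
    icv_labels: frozenset[int]

    def __post_init__(self):
        comps = tuple(self.compartments)
        if not comps:
            raise ValueError("compartment list is empty")
        ids = [c.label_id for c in comps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate label_id in phantom spec")
        tubes = [c for c in comps if c.is_tube]
        if len(tubes) != 6:
            raise ValueError(f"expected exactly six tube compartments, got {len(tubes)}")
        concs = sorted(c.true_tsc for c in tubes)
        if concs[0] < 25.0 - 1e-9 or concs[-1] > 100.0 + 1e-9:
            raise ValueError("tube concentrations must lie within 25-100 mmol/L")
        if any(t.label_id in self.icv_labels for t in tubes):
            raise ValueError("tubes must not be counted as intracranial")
        object.__setattr__(self, "compartments", comps)
        object.__setattr__(self, "icv_labels", frozenset(self.icv_labels))

    @property
    def tube_concentrations(self) -> dict[int, float]:
        return {c.label_id: c.true_tsc for c in self.compartments if c.is_tube}

    @property
    def roi_labels(self) -> dict[str, int]:
        return {
            c.name: c.label_id
            for c in self.compartments
            if c.name in ROI_NAMES
        }


@dataclass
class LabeledPhantom:
    """Rendered phantom: integer labels plus voxelwise ground truth."""

    label_volume: np.ndarray
    truth_tsc_volume: np.ndarray
    truth_params: dict[int, tuple[float, float, float]]  # label -> (t2s, t2l, f)
    voxel_size: float
    spec: PhantomSpec = field(repr=False, default=None)


@dataclass
class MultiEchoImage:
    """4-D magnitude image stack, one volume per echo time."""

    data: np.ndarray  # (x, y, z, n_echo)
    schedule: EchoSchedule
    voxel_size: float

    def __post_init__(self):
        if self.data.shape[-1] != len(self.schedule):
            raise ValueError("4th dimension must match schedule length")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("magnitude images must be finite and >= 0")


@dataclass
class CohortGroundTruth:
    """Per-subject ground truth drawn by the cohort sampler."""

    subject_id: str
    group: str  # "iPD" | "HC"
    roi_tsc: dict[str, float]
    roi_volume_frac: dict[str, float]


# --------------------------------------------------------------------------
# default geometry


def default_phantom_spec(
    roi_tsc: dict[str, float] | None = None,
    grid_size: int = 48,
    voxel_size: float = 3.0,
    tube_concentrations: tuple[float, ...] = DEFAULT_TUBE_CONCENTRATIONS,
    wm_tsc: float = DEFAULT_WM_TSC,
    csf_tsc: float = DEFAULT_CSF_TSC,
    t2_short: float = DEFAULT_T2_SHORT,
    t2_long: float = DEFAULT_T2_LONG,
    short_fraction: float = DEFAULT_SHORT_FRACTION,
) -> PhantomSpec:
    """Default head-and-tubes phantom on a ``grid_size``³ isotropic grid.

    The brain occupies a central sphere (ICV): a white-matter ball carrying
    five embedded deep-gray ellipsoids (substantia nigra, putamen, caudate,
    pallidum, thalamus, sized in rough proportion to their normalized
    volumes), a central CSF sphere, and a cortical gray-matter shell.  Six
    reference tubes sit in a ring below the brain, outside the ICV but inside
    the field of view.  ``roi_tsc`` overrides the per-ROI ground-truth TSC
    (defaults to the iPD group means).
    """
    if grid_size < 24:
        raise ValueError("default geometry requires grid_size >= 24")
    tsc = dict(_IPD_TSC_MEANS)
    if roi_tsc:
        unknown = set(roi_tsc) - set(ROI_NAMES)
        if unknown:
            raise ValueError(f"unknown ROI name(s): {sorted(unknown)}")
        tsc.update(roi_tsc)

    s = grid_size / 48.0
    c = (grid_size - 1) / 2.0

    def ctr(dx, dy, dz):
        return (c + dx * s, c + dy * s, c + dz * s)

    def rad(*r):
        return tuple(max(ri * s, 0.6) for ri in r)

    relax = dict(t2_short=t2_short, t2_long=t2_long, short_fraction=short_fraction)
    comps = [
        CompartmentSpec(1, "SN", tsc["SN"], Geometry("ellipsoid", ctr(0, -4, -7), rad(1.8, 1.4, 1.2)), **relax),
        CompartmentSpec(2, "putamen", tsc["putamen"], Geometry("ellipsoid", ctr(8, 0, 0), rad(3.7, 2.9, 2.3)), **relax),
        CompartmentSpec(3, "caudate", tsc["caudate"], Geometry("ellipsoid", ctr(-7, 3, 2), rad(3.3, 2.7, 2.1)), **relax),
        CompartmentSpec(4, "pallidum", tsc["pallidum"], Geometry("ellipsoid", ctr(4, -6, 0), rad(2.6, 2.1, 1.7)), **relax),
        CompartmentSpec(5, "thalamus", tsc["thalamus"], Geometry("ellipsoid", ctr(0, 7, 1), rad(4.2, 3.2, 2.9)), **relax),
        CompartmentSpec(6, "cortical_gm", tsc["cortical_gm"], Geometry("shell", ctr(0, 0, 0), (13.0 * s, 16.0 * s)), **relax),
        CompartmentSpec(8, "csf", csf_tsc, Geometry("sphere", ctr(0, 0, 0), (max(3.0 * s, 1.0),)), **relax),
        # white matter fills the remainder of the inner ball (rendered last)
        CompartmentSpec(7, "wm", wm_tsc, Geometry("fill_sphere", ctr(0, 0, 0), (13.0 * s,)), **relax),
    ]
    concs = tuple(sorted(tube_concentrations))
    for k, conc in enumerate(concs):
        theta = 2.0 * np.pi * k / len(concs)
        comps.append(
            CompartmentSpec(
                11 + k,
                f"tube_{int(round(conc))}",
                conc,
                Geometry(
                    "sphere",
                    (c + 20.0 * s * np.cos(theta), c + 20.0 * s * np.sin(theta), c - 19.0 * s),
                    (max(2.2 * s, 1.0),),
                ),
                is_tube=True,
                **relax,
            )
        )
    return PhantomSpec(
        grid_shape=(grid_size,) * 3,
        voxel_size=voxel_size,
        compartments=tuple(comps),
        icv_labels=frozenset({1, 2, 3, 4, 5, 6, 7, 8}),
    )


_IPD_TSC_MEANS = {k: v[0] for k, v in _IPD_TSC.items()}


# --------------------------------------------------------------------------
# rendering and simulation


def build_phantom(spec: PhantomSpec, seed: int = 0) -> LabeledPhantom:
    """Render a :class:`PhantomSpec` into label and ground-truth volumes.

    Deterministic for a fixed spec; ``seed`` is accepted for interface
    stability (reserved for stochastic geometry) and currently unused.
    Explicit shapes are rendered first and must be pairwise disjoint;
    ``fill_sphere`` compartments claim the leftover voxels afterwards.
    Every compartment must render at least one voxel.
    """
    del seed
    shape = tuple(spec.grid_shape)
    labels = np.zeros(shape, dtype=np.int32)
    owner = {}
    explicit = [cc for cc in spec.compartments if cc.geometry.kind != "fill_sphere"]
    fills = [cc for cc in spec.compartments if cc.geometry.kind == "fill_sphere"]
    for comp in explicit:
        m = comp.geometry.mask(shape)
        if not m.any():
            raise ValueError(f"compartment {comp.name!r} renders zero voxels")
        clash = m & (labels != 0)
        if clash.any():
            other = int(labels[clash][0])
            raise ValueError(
                f"compartments overlap: {comp.name!r} (label {comp.label_id}) "
                f"and {owner[other]!r} (label {other})"
            )
        labels[m] = comp.label_id
        owner[comp.label_id] = comp.name
    for comp in fills:
        m = comp.geometry.mask(shape, claimed=labels != 0)
        if not m.any():
            raise ValueError(f"compartment {comp.name!r} renders zero voxels")
        labels[m] = comp.label_id
        owner[comp.label_id] = comp.name

    truth = np.zeros(shape, dtype=float)
    params = {}
    for comp in spec.compartments:
        truth[labels == comp.label_id] = comp.true_tsc
        params[comp.label_id] = (comp.t2_short, comp.t2_long, comp.short_fraction)
    return LabeledPhantom(
        label_volume=labels,
        truth_tsc_volume=truth,
        truth_params=params,
        voxel_size=spec.voxel_size,
        spec=spec,
    )


def simulate_multiecho(
    phantom: LabeledPhantom,
    schedule: EchoSchedule | None = None,
    noise_sd: float = 0.0,
    blur_fwhm: float = 0.0,
    seed: int = 0,
    signal_per_mmol: float = 1.0,
) -> MultiEchoImage:
    """Simulate a magnitude multi-echo acquisition of a labeled phantom.

    Each voxel's noiseless signal is the bi-exponential model evaluated at
    that voxel's ground-truth relaxation parameters with S0 proportional to
    its ground-truth TSC (one global constant ``signal_per_mmol``, shared by
    tissue and tubes).  An optional isotropic Gaussian blur of ``blur_fwhm``
    mm (point-spread stand-in) is applied per echo, then Rician noise: the
    magnitude of the signal plus complex Gaussian noise of per-channel
    standard deviation ``noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if blur_fwhm < 0:
        raise ValueError("blur_fwhm must be >= 0")
    schedule = schedule or default_echo_schedule()
    te = schedule.as_array()
    labels = phantom.label_volume
    s0_vol = signal_per_mmol * phantom.truth_tsc_volume

    # per-label unit decay curves, broadcast through a lookup table
    label_ids = np.unique(labels)
    lut = np.zeros((int(label_ids.max()) + 1, te.size))
    for lab in label_ids:
        if lab == 0:
            continue
        t2s, t2l, f = phantom.truth_params[int(lab)]
        lut[lab] = biexp_signal(te, 1.0, f, t2s, t2l)
    data = s0_vol[..., None] * lut[labels]

    if blur_fwhm > 0:
        sigma = blur_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / phantom.voxel_size
        for k in range(te.size):
            data[..., k] = gaussian_filter(data[..., k], sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        n_re = rng.normal(0.0, noise_sd, data.shape)
        n_im = rng.normal(0.0, noise_sd, data.shape)
        data = np.sqrt((data + n_re) ** 2 + n_im**2)
    return MultiEchoImage(data=data, schedule=schedule, voxel_size=phantom.voxel_size)


# --------------------------------------------------------------------------
# cohort sampling


def _draw_truncated_normal(rng, mean, sd):
    # rejection sampling from N(mean, sd) truncated at 0; the acceptance rate
    # is ~1 for all realistic concentration/volume parameters
    if sd == 0:
        return float(mean)
    for _ in range(10000):
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)
    return 0.0


def sample_cohort(
    group_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    n_ipd: int = 10,
    n_hc: int = 12,
    seed: int = 0,
    volume_params: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> list[CohortGroundTruth]:
    """Draw per-subject ground-truth ROI values for a two-group cohort.

    Each ROI value is drawn independently from the group's Gaussian truncated
    at zero (concentrations and volumes cannot be negative).  Defaults
    reproduce the study design: 10 iPD patients and 12 healthy controls with
    the default group means and SDs.  Child seeds are derived per subject
    from ``seed`` so individual subjects are reproducible.
    """
    if n_ipd < 1 or n_hc < 1:
        raise ValueError("both group sizes must be >= 1")
    group_params = group_params or default_group_params()
    volume_params = volume_params or default_volume_params()
    for params in (group_params, volume_params):
        for grp, rois in params.items():
            unknown = set(rois) - set(ROI_NAMES)
            if unknown:
                raise ValueError(f"unknown ROI name(s) in {grp!r} params: {sorted(unknown)}")
            for roi, (_, sd) in rois.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {grp}/{roi}")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_ipd + n_hc)
    cohort = []
    plan = [("iPD", i + 1) for i in range(n_ipd)] + [("HC", i + 1) for i in range(n_hc)]
    for (grp, num), child in zip(plan, children):
        rng = np.random.default_rng(child)
        tsc = {
            roi: _draw_truncated_normal(rng, *group_params[grp][roi])
            for roi in group_params[grp]
        }
        nvol = {
            roi: _draw_truncated_normal(rng, *volume_params[grp][roi])
            for roi in volume_params[grp]
        }
        cohort.append(
            CohortGroundTruth(
                subject_id=f"{grp}{num:02d}", group=grp, roi_tsc=tsc, roi_volume_frac=nvol
            )
        )
    return cohort
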