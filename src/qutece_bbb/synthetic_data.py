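"""Seeded digital-phantom generator.

Produces multi-subject, multi-day 4D datasets (one pre-contrast plus
seven post-contrast volumes per session) with fully known ground truth:
a per-voxel blood-volume field, per-region linear contrast-agent leak
rates, integer-voxel inter-scan motion, a smooth multiplicative z-axis
coil-bias field, Rician magnitude noise, and occasional missing
sessions. The study design emulated is one baseline day followed by
three escalating impact days.

Geometry: an ellipsoidal "brain" partitioned into mirrored left/right
region slabs, flanked by a pure-blood pool sphere, a pure-tissue
reference sphere, and a uniform calibration tube running along z (used
for bias estimation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import AtlasLabels, save_atlas, load_atlas
from .preprocess import ScanSession, reslice_nearest
from .signal_model import (
    AcquisitionParams,
    ContrastAgentParams,
    fe_mass_to_molar,
    relaxation_times,
    steady_state_intensity,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "SubjectTimeline",
    "DAY_LABELS",
    "impact_kinetic_energy",
    "build_atlas",
    "true_region_cbv_series",
    "true_region_slope_pct",
    "simulate_session",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
]

DAY_LABELS = ("baseline", "hit1", "hit2", "hit3")

#: Default scan schedule: pre-contrast 5 min before injection, then
#: seven post-contrast scans every 420 s (~49 min total).
_DEFAULT_SCAN_TIMES = (-300.0, 420.0, 840.0, 1260.0, 1680.0, 2100.0, 2520.0, 2940.0)


def impact_kinetic_energy(mass_kg: float, velocity_m_s: float) -> float:
    """Kinetic energy (J) of the impact device, 0.5 m v^2.

    Ground-truth metadata only; the device itself is not modelled.
    """
    if mass_kg < 0:
        raise ValueError("mass must be >= 0")
    return 0.5 * mass_kg * velocity_m_s**2


@dataclass
class PhantomSpec:
    """Configuration of one phantom cohort.

    ``leak_rates`` are tissue-concentration gains in uM Fe per second
    keyed by region id (absent = 0). ``blood_conc0`` is the starting
    blood concentration in ug/ml Fe; ``blood_halflife`` the
    intravascular clearance half-life in seconds (default ~15 h, so the
    blood pool is nearly constant within a session).
    """

    grid_size: int = 48
    n_regions: int = 10  # bilateral pairs -> 2*n_regions labels
    base_cbv_range: tuple[float, float] = (0.02, 0.06)
    blood_conc0: float = 200.0
    blood_halflife: float = 54000.0
    leak_rates: dict[int, float] = field(default_factory=dict)
    scan_times: tuple[float, ...] = _DEFAULT_SCAN_TIMES
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    motion_max_shift: int = 0
    missing_session_prob: float = 0.0
    seed: int = 0
    proton_density_scale: float = 1000.0

    def __post_init__(self) -> None:
        times = np.asarray(self.scan_times, dtype=float)
        if len(times) != 8 or np.any(np.diff(times) <= 0):
            raise ValueError("scan_times must be 8 strictly increasing values")
        if any(v < 0 for v in self.leak_rates.values()):
            raise ValueError("leak_rates must be >= 0")
        if not 0 <= self.missing_session_prob < 1:
            raise ValueError("missing_session_prob must lie in [0, 1)")
        lo, hi = self.base_cbv_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("base_cbv_range must be an interval inside [0, 1]")

    def acquisition(self) -> AcquisitionParams:
        g = self.grid_size
        return AcquisitionParams(
            matrix_size=(g, g, g),
            field_of_view=(0.03, 0.03, 0.03),
        )


@dataclass
class PhantomTruth:
    """Everything needed to score estimates against the generator.

    ``region_leak_slopes`` stores, per (subject, day), the true
    apparent-CBV slope of each region in percent per second —
    the quantity the biomarker estimates. ``region_leak_rates_um_s``
    keeps the underlying concentration gains for reference.
    """

    cbv_field: np.ndarray
    bias_field: np.ndarray
    seed: int
    region_base_cbv: dict[int, float] = field(default_factory=dict)
    region_leak_slopes: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    region_leak_rates_um_s: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    applied_shifts: dict[str, dict[str, list[list[int]]]] = field(default_factory=dict)
    empirical_snr: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "region_base_cbv": {str(k): v for k, v in self.region_base_cbv.items()},
            "region_leak_slopes": _key_str(self.region_leak_slopes),
            "region_leak_rates_um_s": _key_str(self.region_leak_rates_um_s),
            "applied_shifts": self.applied_shifts,
            "empirical_snr": self.empirical_snr,
        }
        return d


def _key_str(nested):
    return {
        s: {d: {str(r): v for r, v in rv.items()} for d, rv in dv.items()}
        for s, dv in nested.items()
    }


@dataclass
class SubjectTimeline:
    """Ordered (day label, session-or-None) pairs for one subject."""

    subject_id: str
    sessions: list[tuple[str, ScanSession | None]]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.sessions]
        if len(set(days)) != len(days):
            raise ValueError("day labels must be unique")
        baseline = dict(self.sessions).get("baseline")
        if baseline is None:
            raise ValueError("baseline session must be present")

    def session(self, day: str) -> ScanSession | None:
        return dict(self.sessions).get(day)

    @property
    def days(self) -> list[str]:
        return [d for d, _ in self.sessions]


# ---------------------------------------------------------------------------
# geometry


def build_atlas(spec: PhantomSpec) -> AtlasLabels:
    """Ellipsoidal brain tiled into mirrored left/right z-slab regions.

    Labels 1..n are left-hemisphere, n+1..2n their right mirror images.
    Every brain voxel carries exactly one label; reference structures
    (blood pool, tissue reference, calibration tube) live outside the
    brain in separate masks.
    """
    if spec.n_regions < 1:
        raise ValueError("need at least one region pair")
    g = spec.grid_size
    c = (g - 1) / 2.0
    idx = np.indices((g, g, g)).astype(float)
    x, y, z = idx
    semi = (0.30 * g, 0.33 * g, 0.26 * g)
    brain = (
        ((x - c) / semi[0]) ** 2 + ((y - c) / semi[1]) ** 2 + ((z - c) / semi[2]) ** 2
    ) <= 1.0

    left = brain & (x < c)
    labels = np.zeros((g, g, g), dtype=np.int32)
    li, lj, lk = np.nonzero(left)
    order = np.lexsort((lj, li, lk))  # slab regions stacked along z
    chunks = np.array_split(order, spec.n_regions)
    min_voxels = 20
    if any(len(ch) < min_voxels for ch in chunks):
        raise ValueError(
            f"grid {g}^3 too small to host {spec.n_regions} region pairs "
            f"with >= {min_voxels} voxels each"
        )
    for r, ch in enumerate(chunks, start=1):
        labels[li[ch], lj[ch], lk[ch]] = r
    # mirror: right-hemisphere partner labels n+1..2n
    flipped = labels[::-1, :, :]
    right = flipped > 0
    labels[right] = flipped[right] + spec.n_regions

    rows = []
    for r in range(1, spec.n_regions + 1):
        rows.append({"id": r, "name": f"region_{r:02d}", "hemisphere": "left"})
        rows.append({
            "id": r + spec.n_regions,
            "name": f"region_{r:02d}",
            "hemisphere": "right",
        })
    table = pd.DataFrame(rows)

    def _sphere(center, radius):
        return (
            (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        ) <= radius**2

    r_ref = max(2.0, g / 10.0)
    blood = _sphere((c, c, c + semi[2] + r_ref + 1), r_ref)
    tissue = _sphere((c, c, c - semi[2] - r_ref - 1), r_ref)
    tube = ((x - 0.08 * g) ** 2 + (y - c) ** 2) <= (0.06 * g) ** 2
    for name, mask in (("blood pool", blood), ("tissue reference", tissue)):
        if not mask.any() or (mask & brain).any():
            raise ValueError(f"grid too small to place the {name} reference")
    tube &= ~brain & ~blood & ~tissue

    vox = 0.03 / g
    affine = np.diag([vox, vox, vox, 1.0])
    return AtlasLabels(
        labels=labels,
        table=table,
        affine=affine,
        blood_mask=blood,
        tissue_mask=tissue,
        tube_mask=tube,
    )


def _bias_field(spec: PhantomSpec) -> np.ndarray:
    g = spec.grid_size
    z = np.arange(g)
    profile = 1.0 + spec.bias_amplitude * (2.0 * z / (g - 1) - 1.0)
    return np.broadcast_to(profile[None, None, :], (g, g, g)).copy()


def _draw_cbv_field(spec: PhantomSpec, atlas: AtlasLabels, rng) -> tuple[np.ndarray, dict[int, float]]:
    lo, hi = spec.base_cbv_range
    base = {}
    cbv = np.zeros(atlas.labels.shape)
    for pair in range(1, spec.n_regions + 1):
        val = float(rng.uniform(lo, hi))
        for rid in (pair, pair + spec.n_regions):  # bilateral symmetry
            base[rid] = val
            cbv[atlas.labels == rid] = val
    cbv[atlas.blood_mask] = 1.0
    return cbv, base


# ---------------------------------------------------------------------------
# signal generation


def _blood_conc_mM(spec: PhantomSpec, t: float, agent: ContrastAgentParams) -> float:
    if t < 0:
        return 0.0
    c0 = fe_mass_to_molar(spec.blood_conc0, agent.fe_molar_mass)
    return c0 * np.exp(-t * np.log(2.0) / spec.blood_halflife)


def _compartment_intensities(
    spec: PhantomSpec,
    t: float,
    tissue_conc_mM: float,
    acq: AcquisitionParams,
    agent: ContrastAgentParams,
) -> tuple[float, float]:
    """(pure-blood, tissue-at-conc) steady-state intensities at time t."""
    cb = _blood_conc_mM(spec, t, agent)
    s_blood = steady_state_intensity(
        spec.proton_density_scale, *relaxation_times(cb, agent, "blood"), acq
    )
    s_tissue = steady_state_intensity(
        spec.proton_density_scale,
        *relaxation_times(tissue_conc_mM, agent, "tissue"),
        acq,
    )
    return s_blood, s_tissue


def true_region_cbv_series(
    spec: PhantomSpec,
    base_cbv: float,
    leak_rate_um_s: float,
    acq: AcquisitionParams | None = None,
    agent: ContrastAgentParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free apparent-CBV series (post-contrast scans only).

    Closed-form evaluation of the generative equations: the apparent
    CBV a region of fractional blood volume ``f`` and linear tissue
    leak would show when read against pure-blood and pure-tissue
    references. Returns (times, values).
    """
    acq = acq or spec.acquisition()
    agent = agent or ContrastAgentParams()
    times = np.asarray(spec.scan_times[1:], dtype=float)
    values = []
    for t in times:
        ct = leak_rate_um_s * 1e-3 * t  # uM/s * s -> mM
        s_blood, s_tissue = _compartment_intensities(spec, t, ct, acq, agent)
        _, s_tissue0 = _compartment_intensities(spec, t, 0.0, acq, agent)
        voxel = base_cbv * s_blood + (1.0 - base_cbv) * s_tissue
        values.append((voxel - s_tissue0) / (s_blood - s_tissue0))
    return times, np.asarray(values)


def true_region_slope_pct(
    spec: PhantomSpec,
    base_cbv: float,
    leak_rate_um_s: float,
    acq: AcquisitionParams | None = None,
    agent: ContrastAgentParams | None = None,
) -> float:
    """True apparent-CBV slope in percent of intercept per second."""
    times, values = true_region_cbv_series(spec, base_cbv, leak_rate_um_s, acq, agent)
    slope, intercept = np.polyfit(times, values, 1)
    return float(slope / intercept * 100.0)


def _rician(signal: np.ndarray, sigma: float, rng) -> np.ndarray:
    if sigma == 0:
        return signal
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(re**2 + im**2)


def simulate_session(
    spec: PhantomSpec,
    atlas: AtlasLabels,
    cbv_field: np.ndarray,
    day_leaks: dict[int, float],
    rng: np.random.Generator,
    acq: AcquisitionParams | None = None,
    agent: ContrastAgentParams | None = None,
    subject_id: str = "subject",
    day_label: str = "baseline",
) -> tuple[ScanSession, list[list[int]]]:
    """Render one session's 8 volumes; returns (session, applied shifts).

    Per scan: blood concentration decays exponentially from the
    starting dose; tissue concentration in region r grows linearly at
    ``day_leaks[r]`` uM/s; voxel intensity mixes the compartment
    signals by the local blood-volume fraction; the z bias field
    multiplies; Rician noise corrupts; an integer motion shift
    displaces the volume (the first post-contrast scan, the motion
    reference, is never shifted).
    """
    acq = acq or spec.acquisition()
    agent = agent or ContrastAgentParams()
    bias = _bias_field(spec)
    labels = atlas.labels
    shifts: list[list[int]] = []
    volumes: list[np.ndarray] = []

    for k, t in enumerate(spec.scan_times):
        pre = k == 0
        s_blood, s_tissue0 = _compartment_intensities(
            spec, -1.0 if pre else t, 0.0, acq, agent
        )
        tissue_signal = np.full(labels.shape, s_tissue0)
        if not pre:
            for rid, lam in day_leaks.items():
                if lam <= 0:
                    continue
                ct = lam * 1e-3 * t
                _, s_leaked = _compartment_intensities(spec, t, ct, acq, agent)
                tissue_signal[labels == rid] = s_leaked
        clean = cbv_field * s_blood + (1.0 - cbv_field) * tissue_signal
        if atlas.tube_mask is not None:
            # uniform copper-sulfate tube: fixed short-T1 water signal
            s_tube = steady_state_intensity(
                spec.proton_density_scale, 0.3, agent.baseline_T2, acq
            )
            clean[atlas.tube_mask] = s_tube
        vol = _rician(clean * bias, spec.noise_sigma, rng)
        if spec.motion_max_shift > 0 and k != 1:
            shift = rng.integers(
                -spec.motion_max_shift, spec.motion_max_shift + 1, size=3
            ).tolist()
        else:
            shift = [0, 0, 0]
        if any(shift):
            vol = reslice_nearest(vol, shift)
        shifts.append([int(s) for s in shift])
        volumes.append(vol)

    session = ScanSession(
        pre_volume=volumes[0],
        post_volumes=volumes[1:],
        timestamps=np.asarray(spec.scan_times, dtype=float),
        acq=acq,
        affine=atlas.affine.copy(),
        subject_id=subject_id,
        day_label=day_label,
    )
    return session, shifts


def simulate_cohort(
    spec: PhantomSpec,
    n_subjects: int,
    day_effect_profile: dict[str, float] | None = None,
    affected_fraction: float = 0.3,
    leak_jitter: float = 0.4,
    acq: AcquisitionParams | None = None,
    agent: ContrastAgentParams | None = None,
) -> tuple[list[SubjectTimeline], PhantomTruth, AtlasLabels]:
    """Generate a seeded cohort over baseline + three impact days.

    ``day_effect_profile`` maps day label to the mean leak rate (uM/s)
    applied to each subject's randomly chosen affected regions. Each
    affected region gets a lognormal severity multiplier drawn once per
    subject (fixed vulnerable anatomy), so escalating day profiles
    yield region leak rates that escalate for every region.
    Non-baseline sessions are dropped with ``missing_session_prob``.
    All randomness flows from ``spec.seed``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if day_effect_profile is None:
        day_effect_profile = {"baseline": 0.0, "hit1": 0.0005, "hit2": 0.001, "hit3": 0.002}
    acq = acq or spec.acquisition()
    agent = agent or ContrastAgentParams()

    rng = np.random.default_rng(spec.seed)
    atlas = build_atlas(spec)
    cbv_field, base_cbv = _draw_cbv_field(spec, atlas, rng)
    truth = PhantomTruth(
        cbv_field=cbv_field,
        bias_field=_bias_field(spec),
        seed=spec.seed,
        region_base_cbv=base_cbv,
    )

    all_regions = atlas.region_ids
    n_affected = max(1, round(affected_fraction * len(all_regions)))
    timelines = []
    for s in range(n_subjects):
        subject_id = f"sub{s + 1:02d}"
        sub_rng = np.random.default_rng(rng.integers(0, 2**63))
        affected = sub_rng.choice(all_regions, size=n_affected, replace=False)
        severity = {
            int(rid): float(np.exp(sub_rng.normal(0.0, leak_jitter)))
            for rid in affected
        }
        sessions: list[tuple[str, ScanSession | None]] = []
        for day in DAY_LABELS:
            if day != "baseline" and sub_rng.random() < spec.missing_session_prob:
                sessions.append((day, None))
                continue
            mean_rate = float(day_effect_profile.get(day, 0.0))
            leaks: dict[int, float] = dict(spec.leak_rates)
            if mean_rate > 0:
                for rid in affected:
                    leaks[int(rid)] = mean_rate * severity[int(rid)]
            session, shifts = simulate_session(
                spec, atlas, cbv_field, leaks, sub_rng,
                acq=acq, agent=agent, subject_id=subject_id, day_label=day,
            )
            sessions.append((day, session))
            truth.applied_shifts.setdefault(subject_id, {})[day] = shifts
            truth.region_leak_rates_um_s.setdefault(subject_id, {})[day] = {
                int(r): float(v) for r, v in leaks.items()
            }
            truth.region_leak_slopes.setdefault(subject_id, {})[day] = {
                int(rid): true_region_slope_pct(
                    spec, base_cbv[int(rid)], leaks.get(int(rid), 0.0), acq, agent
                )
                for rid in all_regions
            }
            if spec.noise_sigma > 0:
                brain_mean = float(session.post_volumes[0][atlas.brain_mask].mean())
                truth.empirical_snr.setdefault(subject_id, {})[day] = (
                    brain_mean / spec.noise_sigma
                )
        timelines.append(SubjectTimeline(subject_id=subject_id, sessions=sessions))
    return timelines, truth, atlas


# ---------------------------------------------------------------------------
# disk layout: cohort/<subject>/<day>/scan_<k>.nii.gz + JSON sidecars


def write_cohort(
    out_dir: str | Path,
    timelines: list[SubjectTimeline],
    truth: PhantomTruth,
    atlas: AtlasLabels,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_atlas(atlas, out_dir / "atlas")
    nib.save(
        nib.Nifti1Image(truth.cbv_field.astype(np.float32), atlas.affine),
        out_dir / "truth_cbv_field.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(truth.bias_field.astype(np.float32), atlas.affine),
        out_dir / "truth_bias_field.nii.gz",
    )
    (out_dir / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=2))

    manifest = []
    for tl in timelines:
        entry = {"subject_id": tl.subject_id, "sessions": []}
        for day, session in tl.sessions:
            if session is None:
                entry["sessions"].append({"day": day, "missing": True})
                continue
            sess_dir = out_dir / tl.subject_id / day
            sess_dir.mkdir(parents=True, exist_ok=True)
            for k, vol in enumerate(session.all_volumes()):
                nib.save(
                    nib.Nifti1Image(vol.astype(np.float32), session.affine),
                    sess_dir / f"scan_{k:02d}.nii.gz",
                )
            entry["sessions"].append({
                "day": day,
                "missing": False,
                "timestamps": session.timestamps.tolist(),
                "acq": asdict(session.acq),
            })
        manifest.append(entry)
    (out_dir / "cohort.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_cohort(in_dir: str | Path) -> tuple[list[SubjectTimeline], AtlasLabels]:
    in_dir = Path(in_dir)
    atlas = load_atlas(in_dir / "atlas")
    manifest = json.loads((in_dir / "cohort.json").read_text())
    timelines = []
    for entry in manifest:
        sessions: list[tuple[str, ScanSession | None]] = []
        for srec in entry["sessions"]:
            if srec["missing"]:
                sessions.append((srec["day"], None))
                continue
            sess_dir = in_dir / entry["subject_id"] / srec["day"]
            vols = [
                np.asarray(nib.load(p).dataobj, dtype=float)
                for p in sorted(sess_dir.glob("scan_*.nii.gz"))
            ]
            acq_d = dict(srec["acq"])
            acq_d["matrix_size"] = tuple(acq_d["matrix_size"])
            acq_d["field_of_view"] = tuple(acq_d["field_of_view"])
            sessions.append((
                srec["day"],
                ScanSession(
                    pre_volume=vols[0],
                    post_volumes=vols[1:],
                    timestamps=np.asarray(srec["timestamps"]),
                    acq=AcquisitionParams(**acq_d),
                    affine=atlas.affine.copy(),
                    subject_id=entry["subject_id"],
                    day_label=srec["day"],
                ),
            ))
        timelines.append(SubjectTimeline(subject_id=entry["subject_id"], sessions=sessions))
    return timelines, atlas
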