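"""From peak intensities to per-patient metabolite-entity Z-score profiles.

Direct-infusion metabolomics yields one intensity per m/z peak per
injection.  This module annotates peaks against a monoisotopic mass table
(±2 ppm by default, within the 70-600 m/z scan range), collapses isomers
that share a matched mass into a single *entity* with multiple
annotations, and converts intensities into control-referenced Z-scores:

    Z = (intensity_patient - mean(control intensities)) / sd(control intensities)

Technical replicate intensities are averaged per sample before the control
statistics are computed; the standard deviation uses the sample (n-1)
convention, appropriate for the small control cohorts (n ≈ 30) this is
designed for.  Z-scores are produced for controls as well as patients, so
the control Z distribution can be checked (≈ N(0, 1)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

DEFAULT_PPM = 2.0
DEFAULT_SCAN_RANGE = (70.0, 600.0)

CONTROL_ROLE = "control"


@dataclass
class PeakTable:
    """Peak intensities plus the sample manifest.

    ``intensities`` is indexed by peak (rows, aligned with ``mz``) with a
    two-level column index (sample id, replicate index).  ``roles`` maps
    sample id -> "control" or a patient id.
    """

    mz: np.ndarray
    intensities: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self):
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise InputError("intensities must be finite and non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns.get_level_values(0).unique())

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.samples if self.roles.get(s) == CONTROL_ROLE]

    @property
    def patient_of(self) -> dict[str, str]:
        """Sample id -> patient id, for non-control samples."""
        return {s: r for s, r in self.roles.items() if r != CONTROL_ROLE}


@dataclass(frozen=True)
class MetaboliteEntity:
    """A measured entity: one peak plus the isomeric metabolites it matches."""

    entity_id: str
    mz: float
    annotations: frozenset[str]

    def __post_init__(self):
        if not self.annotations:
            raise InputError("an entity needs at least one annotation")


@dataclass
class ZScoreProfile:
    """Per-sample (or per-patient, after averaging) entity Z-scores.

    ``flagged`` holds entities whose control standard deviation was zero:
    their Z is undefined (NaN) and they are excluded from enrichment
    downstream rather than silently dropped here.
    """

    owner: str
    z: dict[str, float]
    annotations: dict[str, frozenset[str]]
    flagged: frozenset[str] = field(default_factory=frozenset)

    @property
    def entities(self) -> frozenset[str]:
        return frozenset(self.z)

    def measured_entities(self) -> frozenset[str]:
        """Entities usable for enrichment: annotated, with finite Z."""
        return frozenset(e for e in self.z if e not in self.flagged)


def load_peak_table(peaks_path, manifest_path) -> PeakTable:
    """Read the TSV peak table and sample manifest.

    The peak table has a ``mz`` column and one column per injection named
    ``<sample>#<replicate>``.  The manifest is tab-separated with columns
    ``sample``, ``role`` ("control" or "patient") and, for patients,
    ``patient_id``.
    """
    df = pd.read_csv(peaks_path, sep="\t")
    if "mz" not in df.columns:
        raise InputError("peak table missing 'mz' column")
    sample_cols = [c for c in df.columns if c != "mz"]
    parsed = []
    for c in sample_cols:
        if "#" not in c:
            raise InputError(f"peak column {c!r} is not of the form 'sample#replicate'")
        sample, rep = c.rsplit("#", 1)
        parsed.append((sample, int(rep)))
    intensities = df[sample_cols].astype(float)
    intensities.columns = pd.MultiIndex.from_tuples(parsed, names=["sample", "replicate"])

    man = pd.read_csv(manifest_path, sep="\t", dtype=str)
    if not {"sample", "role"} <= set(man.columns):
        raise InputError("manifest missing 'sample'/'role' columns")
    roles: dict[str, str] = {}
    for row in man.itertuples(index=False):
        role = str(row.role).strip().lower()
        if role == CONTROL_ROLE:
            roles[str(row.sample)] = CONTROL_ROLE
        else:
            pid = getattr(row, "patient_id", None)
            pid = str(pid).strip() if pid is not None and str(pid) != "nan" else str(row.sample)
            roles[str(row.sample)] = pid
    missing = set(intensities.columns.get_level_values(0)) - set(roles)
    if missing:
        raise InputError(f"samples absent from manifest: {sorted(missing)}")
    return PeakTable(df["mz"].to_numpy(dtype=float), intensities, roles)


def load_mass_table(path) -> dict[str, float]:
    """Read a mass table: tab-separated ``metabolite_id``, ``mass`` (Da)."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise InputError("mass table needs metabolite_id and mass columns")
    masses = {}
    for row in df.itertuples(index=False):
        mass = float(row[1])
        if mass <= 0:
            raise InputError(f"non-positive mass for {row[0]!r}")
        masses[str(row[0])] = mass
    return masses


def annotate_peaks(
    peaks: PeakTable,
    masses: dict[str, float],
    ppm_window: float = DEFAULT_PPM,
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
) -> list[tuple[int, MetaboliteEntity]]:
    """Match peaks to metabolites within a relative ppm window.

    Returns ``(peak index, entity)`` pairs for every peak inside
    ``scan_range`` that matches at least one metabolite mass within
    ``±ppm_window`` parts per million of the peak m/z.  Isomers matched by
    the same peak are collapsed into a single entity carrying all their
    ids.  Peaks with no match are silently unannotated (a warning is
    emitted if the mass table is empty).
    """
    if ppm_window <= 0:
        raise ConfigurationError("ppm_window must be positive")
    if not masses:
        warnings.warn("empty mass table: no peak can be annotated", stacklevel=2)
        return []
    ids = np.array(list(masses))
    mvals = np.array([masses[i] for i in ids], dtype=float)
    order = np.argsort(mvals)
    ids, mvals = ids[order], mvals[order]

    lo, hi = scan_range
    out: list[tuple[int, MetaboliteEntity]] = []
    for idx in np.argsort(peaks.mz, kind="stable"):
        mz = float(peaks.mz[idx])
        if not (lo <= mz <= hi):
            continue
        tol = mz * ppm_window * 1e-6
        a = np.searchsorted(mvals, mz - tol, side="left")
        b = np.searchsorted(mvals, mz + tol, side="right")
        if b > a:
            matched = frozenset(ids[a:b])
            entity = MetaboliteEntity(f"E{idx:05d}", mz, matched)
            out.append((int(idx), entity))
    out.sort(key=lambda pair: pair[0])
    return out


def compute_zscores(
    peaks: PeakTable,
    annotated: list[tuple[int, MetaboliteEntity]],
    leave_one_out: bool = False,
) -> dict[str, ZScoreProfile]:
    """Control-referenced Z-scores for every sample, per annotated entity.

    Replicate intensities are averaged per sample first; the control mean
    and sample (n-1) standard deviation are then taken over the per-sample
    averages.  By default a control's own average is part of the reference
    statistics (``leave_one_out=True`` recomputes the reference without the
    sample itself, for sensitivity analysis).  Entities with zero control
    standard deviation are flagged and their Z set to NaN.
    """
    controls = peaks.control_samples
    if len(controls) < 2:
        raise ConfigurationError(
            f"need at least 2 control samples for a standard deviation, got {len(controls)}"
        )
    # per-sample replicate means, rows = peaks
    per_sample = peaks.intensities.T.groupby(level="sample").mean().T
    samples = list(per_sample.columns)
    ctrl = per_sample[controls].to_numpy(dtype=float)
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)

    profiles: dict[str, ZScoreProfile] = {}
    annot_map = {e.entity_id: e.annotations for _, e in annotated}
    for s in samples:
        x = per_sample[s].to_numpy(dtype=float)
        if leave_one_out and s in controls:
            others = [c for c in controls if c != s]
            sub = per_sample[others].to_numpy(dtype=float)
            mu, sigma = sub.mean(axis=1), sub.std(axis=1, ddof=1)
        else:
            mu, sigma = mean, sd
        with np.errstate(divide="ignore", invalid="ignore"):
            zvec = (x - mu) / sigma
        z: dict[str, float] = {}
        flagged = set()
        for idx, entity in annotated:
            if sigma[idx] > 0:
                z[entity.entity_id] = float(zvec[idx])
            else:
                z[entity.entity_id] = float("nan")
                flagged.add(entity.entity_id)
        profiles[s] = ZScoreProfile(s, z, dict(annot_map), frozenset(flagged))
    return profiles


def average_patient_profiles(profiles: list[ZScoreProfile], owner: str | None = None) -> ZScoreProfile:
    """Entity-wise mean of several Z-score profiles of one patient.

    All profiles must share the same entity universe; entities flagged for
    zero control variance in any contributing profile stay flagged.
    """
    if not profiles:
        raise ConfigurationError("need at least one profile to average")
    universe = profiles[0].entities
    for p in profiles[1:]:
        if p.entities != universe:
            diff = universe.symmetric_difference(p.entities)
            raise InputError(f"profiles have mismatched entity universes: {sorted(diff)[:5]}...")
    flagged = frozenset().union(*(p.flagged for p in profiles))
    z = {e: float(np.mean([p.z[e] for p in profiles])) for e in universe}
    return ZScoreProfile(owner or profiles[0].owner, z, dict(profiles[0].annotations), flagged)


def profiles_by_patient(
    peaks: PeakTable, annotated: list[tuple[int, MetaboliteEntity]], **kwargs
) -> dict[str, ZScoreProfile]:
    """One averaged Z-score profile per patient (multiple samples averaged)."""
    sample_profiles = compute_zscores(peaks, annotated, **kwargs)
    grouped: dict[str, list[ZScoreProfile]] = {}
    for sample, patient in peaks.patient_of.items():
        grouped.setdefault(patient, []).append(sample_profiles[sample])
    return {pid: average_patient_profiles(plist, owner=pid) for pid, plist in grouped.items()}


def aberrant_entities(profile: ZScoreProfile, thresholds: tuple[float, float]) -> frozenset[str]:
    """Entities whose Z falls strictly below L or strictly above U.

    ``thresholds`` is the paired biochemical stringency (L, U) with
    L < 0 < U; a Z equal to a threshold is *not* aberrant.  Flagged
    (zero-variance) entities are never aberrant.
    """
    low, high = thresholds
    if not (low < 0 < high):
        raise ConfigurationError(f"thresholds must satisfy L < 0 < U, got {thresholds}")
    return frozenset(
        e
        for e, zval in profile.z.items()
        if e not in profile.flagged and (zval < low or zval > high)
    )


def save_profile(profile: ZScoreProfile, path) -> None:
    """Write a profile as TSV: entity_id, annotations (semicolon-joined), z."""
    rows = [
        {
            "entity_id": e,
            "annotations": ";".join(sorted(profile.annotations[e])),
            "z": profile.z[e],
            "flagged": int(e in profile.flagged),
        }
        for e in sorted(profile.z)
    ]
    pd.DataFrame(rows, columns=["entity_id", "annotations", "z", "flagged"]).to_csv(
        path, sep="\t", index=False
    )


def load_profile(path, owner: str | None = None) -> ZScoreProfile:
    df = pd.read_csv(path, sep="\t", dtype={"entity_id": str, "annotations": str})
    z, annotations, flagged = {}, {}, set()
    for row in df.itertuples(index=False):
        e = str(row.entity_id)
        z[e] = float(row.z)
        annotations[e] = frozenset(str(row.annotations).split(";"))
        if getattr(row, "flagged", 0):
            flagged.add(e)
    return ZScoreProfile(owner or "profile", z, annotations, frozenset(flagged))
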