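"""End-to-end run configuration and execution.

A run is described by one YAML document naming every input table, the
parameter combination, and the output directory.  Validation happens
up-front — every referenced path is checked before any computation — and
every parameter actually used is echoed into a JSON run manifest next to
the outputs, so no run depends on silent defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError, InputError
from .metabolomics import annotate_peaks, load_mass_table, load_peak_table, profiles_by_patient
from .network import (
    DEFAULT_BLACKLIST,
    load_blacklist,
    load_gene_map,
    load_network,
    remove_nonspecific,
)
from .prioritization import listing_to_frame, prioritize
from .sets import ExtensionParams, build_all_sets


def read_gene_list(path) -> list[str]:
    """Plain-text candidate list: one gene name per line, '#' comments allowed."""
    genes = []
    with open(path) as fh:
        for line in fh:
            tok = line.split("#", 1)[0].strip()
            if tok:
                genes.append(tok)
    if not genes:
        raise InputError(f"empty gene list: {path}")
    return genes


@dataclass
class RunConfig:
    """Validated inputs and parameters for one cross-omics run."""

    reactions: Path
    gene_map: Path
    masses: Path
    peaks: Path
    manifest: Path
    candidates: dict[str, Path]  # patient id -> candidate list ("*" = shared)
    max_distance: int = 4
    extension_stringency: int = 15
    thresholds: tuple[float, float] = (-3.0, 3.0)
    blacklist: Path | None = None
    ppm: float = 2.0
    output_dir: Path = field(default_factory=lambda: Path("crossomics_out"))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            params = doc.get("params", {})
            cand = doc["candidates"]
            if isinstance(cand, str):
                cand = {"*": cand}
            cfg = cls(
                reactions=Path(doc["reactions"]),
                gene_map=Path(doc["gene_map"]),
                masses=Path(doc["masses"]),
                peaks=Path(doc["peaks"]),
                manifest=Path(doc["manifest"]),
                candidates={k: Path(v) for k, v in cand.items()},
                max_distance=int(params.get("max_distance", 4)),
                extension_stringency=int(params.get("extension_stringency", 15)),
                thresholds=tuple(params.get("bst", (-3.0, 3.0))),
                blacklist=Path(doc["blacklist"]) if doc.get("blacklist") else None,
                ppm=float(doc.get("ppm", 2.0)),
                output_dir=Path(doc.get("output_dir", "crossomics_out")),
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: missing config key {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.reactions, self.gene_map, self.masses, self.peaks, self.manifest]
        paths += list(self.candidates.values())
        if self.blacklist is not None:
            paths.append(self.blacklist)
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigurationError(f"input file(s) not found: {missing}")
        low, high = self.thresholds
        if not low < 0 < high:
            raise ConfigurationError(f"thresholds must satisfy L < 0 < U, got {self.thresholds}")

    def manifest_dict(self) -> dict:
        return {
            "version": __version__,
            "reactions": str(self.reactions),
            "gene_map": str(self.gene_map),
            "masses": str(self.masses),
            "peaks": str(self.peaks),
            "manifest": str(self.manifest),
            "candidates": {k: str(v) for k, v in self.candidates.items()},
            "max_distance": self.max_distance,
            "extension_stringency": self.extension_stringency,
            "bst": list(self.thresholds),
            "blacklist": str(self.blacklist) if self.blacklist else "builtin-default",
            "ppm": self.ppm,
            "output_dir": str(self.output_dir),
        }


def run_crossomics(config: RunConfig) -> dict[str, int]:
    """Execute the full per-patient pipeline described by ``config``.

    Builds (blacklist-filtered) gene sets once, computes per-patient
    Z-score profiles, prioritizes each patient's candidate list, and
    writes ``<patient>.ranked.tsv`` files plus ``summary.tsv`` and
    ``run_manifest.json`` to the output directory.  Returns a map patient
    id -> number of ranked genes.
    """
    config.validate()
    out = Path(config.output_dir)

    blacklist = (
        load_blacklist(config.blacklist) if config.blacklist is not None else DEFAULT_BLACKLIST
    )
    network = remove_nonspecific(load_network(config.reactions), blacklist)
    gene_map = load_gene_map(config.gene_map)
    params = ExtensionParams(
        max_distance=config.max_distance,
        extension_stringency=config.extension_stringency,
        blacklist=frozenset(blacklist),
    )
    sets = build_all_sets(gene_map, network, params)

    peaks = load_peak_table(config.peaks, config.manifest)
    masses = load_mass_table(config.masses)
    annotated = annotate_peaks(peaks, masses, ppm_window=config.ppm)
    profiles = profiles_by_patient(peaks, annotated)

    out.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    written: dict[str, int] = {}
    for pid in sorted(profiles):
        cand_path = config.candidates.get(pid, config.candidates.get("*"))
        if cand_path is None:
            raise ConfigurationError(f"no candidate list for patient {pid!r}")
        candidates = read_gene_list(cand_path)
        listing = prioritize(candidates, sets, profiles[pid], config.thresholds)
        frame = listing_to_frame(listing)
        frame.to_csv(out / f"{pid}.ranked.tsv", sep="\t", index=False)
        written[pid] = len(listing)
        best = listing.entries[0]
        summary_rows.append(
            {
                "patient_id": pid,
                "n_candidates": len(listing),
                "n_missed": sum(r.missed for r in listing.entries),
                "top_gene": best.gene,
                "top_p_value": best.p_value,
            }
        )
    import pandas as pd

    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(config.manifest_dict(), fh, indent=1)
    return written
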