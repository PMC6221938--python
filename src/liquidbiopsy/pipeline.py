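"""Per-patient orchestration: target selection, plasma quantification, CNV.

A patient case is described by a YAML/JSON document pointing at the input
files; ``run_case`` composes the stage operations deterministically and
emits a versioned, JSON-serializable report. Missing inputs produce
explicit ``not_computed`` sections, never silent omission.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from . import io as lio
from .cnv import (
    CNVProfile,
    compare_profiles,
    compute_logr,
    instability_score,
    make_bins,
)
from .ddpcr import QuantConfig, merge_wells, quantify
from .genome import GenomeBuild
from .variants import SelectionConfig, select_target

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


@dataclass
class PatientCase:
    """Resolved description of one patient's inputs.

    All paths are absolute (resolved against the case file's directory).
    """

    patient_id: str
    disease_status: str = "localized"
    variants_path: Optional[Path] = None
    chrom_sizes_path: Optional[Path] = None
    bin_size: int = 50_000
    normal_counts_path: Optional[Path] = None
    tumor_counts_path: Optional[Path] = None
    plasma_counts_paths: dict[str, Path] = field(default_factory=dict)
    plasma_droplets_paths: dict[str, Path] = field(default_factory=dict)
    config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.disease_status not in ("localized", "metastatic"):
            raise ValueError("disease_status must be 'localized' or 'metastatic'")
        if not self.timepoints:
            raise ValueError("case needs at least one plasma timepoint")
        for path in self._all_paths():
            if not Path(path).exists():
                raise FileNotFoundError(f"case references missing file: {path}")

    def _all_paths(self):
        for p in (
            self.variants_path,
            self.chrom_sizes_path,
            self.normal_counts_path,
            self.tumor_counts_path,
        ):
            if p is not None:
                yield p
        yield from self.plasma_counts_paths.values()
        yield from self.plasma_droplets_paths.values()

    @property
    def timepoints(self) -> list[str]:
        return sorted(set(self.plasma_droplets_paths) | set(self.plasma_counts_paths))

    @classmethod
    def from_yaml(cls, path) -> "PatientCase":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p):
            return None if p is None else (base / p).resolve()

        cnv = doc.get("cnv") or {}
        return cls(
            patient_id=str(doc["patient_id"]),
            disease_status=doc.get("disease_status", "localized"),
            variants_path=resolve(doc.get("variants")),
            chrom_sizes_path=resolve(doc.get("genome")),
            bin_size=int(doc.get("bin_size", 50_000)),
            normal_counts_path=resolve(cnv.get("normal_counts")),
            tumor_counts_path=resolve(cnv.get("tumor_counts")),
            plasma_counts_paths={
                str(k): resolve(v) for k, v in (cnv.get("plasma_counts") or {}).items()
            },
            plasma_droplets_paths={
                str(k): resolve(v) for k, v in (doc.get("plasma_droplets") or {}).items()
            },
            config=doc.get("config") or {},
        )


def _not_computed(reason: str) -> dict:
    return {"status": "not_computed", "reason": reason}


def _resolved_config(case: PatientCase, overrides: Optional[Mapping] = None) -> dict:
    config = {
        "selection": dict(case.config.get("selection") or {}),
        "quant": dict(case.config.get("quant") or {}),
        "cnv": dict(case.config.get("cnv") or {}),
    }
    for section, values in (overrides or {}).items():
        config.setdefault(section, {}).update(values)
    return config


def run_case(case: PatientCase, overrides: Optional[Mapping] = None) -> dict:
    """Run selection, per-timepoint quantification and CNV for one case.

    Returns the JSON-ready report dict. Sections without inputs carry
    ``{"status": "not_computed", "reason": ...}``; everything else is
    traceable to one stage operation. Deterministic given inputs+config.
    """
    config = _resolved_config(case, overrides)
    sel_cfg = SelectionConfig(**config["selection"])
    quant_cfg = QuantConfig(**config["quant"])
    cnv_cfg = config["cnv"]
    min_normal = int(cnv_cfg.get("min_normal_count", 10))
    logr_threshold = float(cnv_cfg.get("logr_threshold", 0.15))

    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "patient_id": case.patient_id,
        "disease_status": case.disease_status,
    }

    # --- target selection ---------------------------------------------------
    if case.variants_path is None:
        report["selection"] = _not_computed("no variant table provided")
    else:
        variants = lio.read_variant_table(case.variants_path)
        result = select_target(variants, sel_cfg)
        logger.info(
            "selection: %d in, %d survivors, target=%s",
            len(variants),
            len(result.survivors),
            result.target.key if result.target else None,
        )
        report["selection"] = {"status": "computed", **result.to_dict()}

    # --- plasma quantification ---------------------------------------------
    quant_section: dict[str, Any] = {}
    for tp in case.timepoints:
        droplets = case.plasma_droplets_paths.get(tp)
        if droplets is None:
            quant_section[tp] = _not_computed("no droplet data for timepoint")
            continue
        wells = lio.read_droplet_counts(droplets)
        merged = merge_wells(wells)
        result = quantify(merged, quant_cfg)
        logger.info("quant %s: %d wells, vaf=%.4f", tp, len(wells), result.vaf)
        quant_section[tp] = {
            "status": "computed",
            "n_wells": len(wells),
            "n_accepted": merged.n_accepted,
            **{k: v for k, v in result.to_dict().items()},
        }
    report["quant"] = quant_section or _not_computed("no plasma droplet data")

    # --- CNV ----------------------------------------------------------------
    report["cnv"] = _run_cnv(case, min_normal, logr_threshold)

    resolved = {
        "selection": _dataclass_dict(sel_cfg),
        "quant": _dataclass_dict(quant_cfg),
        "cnv": {"min_normal_count": min_normal, "logr_threshold": logr_threshold},
    }
    report["provenance"] = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "config": resolved,
        "config_hash": hashlib.sha256(
            lio.dumps_canonical(resolved).encode()
        ).hexdigest(),
    }
    return report


def _dataclass_dict(obj) -> dict:
    from dataclasses import asdict

    return asdict(obj)


def _run_cnv(case: PatientCase, min_normal: int, logr_threshold: float) -> dict:
    if case.chrom_sizes_path is None or case.normal_counts_path is None:
        return _not_computed("genome or normal counts missing")
    build = GenomeBuild.from_chrom_sizes(case.chrom_sizes_path)
    binning = make_bins(build, case.bin_size)
    normal = lio.read_counts(case.normal_counts_path, binning, sample_id="normal")

    profiles: dict[str, CNVProfile] = {}
    if case.tumor_counts_path is not None:
        tumor = lio.read_counts(case.tumor_counts_path, binning, sample_id="tumor")
        profiles["tumor"] = compute_logr(tumor, normal, min_normal)
    for tp, path in sorted(case.plasma_counts_paths.items()):
        counts = lio.read_counts(path, binning, sample_id=tp)
        profiles[tp] = compute_logr(counts, normal, min_normal)

    if not profiles:
        return _not_computed("no tumor or plasma count tables")

    section: dict[str, Any] = {"status": "computed", "bin_size": case.bin_size}
    section["instability"] = {
        name: instability_score(p, logr_threshold) for name, p in profiles.items()
    }
    comparisons: dict[str, Any] = {}
    names = list(profiles)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            cmp = compare_profiles(profiles[a], profiles[b])
            comparisons[f"{a}_vs_{b}"] = {
                "r": cmp.r,
                "p": cmp.p,
                "p_text": cmp.p_text,
                "n_bins": cmp.n_bins,
            }
    section["comparisons"] = comparisons
    return section


def write_report(report: dict, path) -> None:
    lio.write_json(report, path)


def longitudinal_summary(reports: Sequence[dict]) -> pd.DataFrame:
    """Per-timepoint VAF / copies-per-mL / instability trend with deltas.

    Accepts one or more reports of the same patient; the union of their
    computed quant timepoints (sorted by name) must cover at least two
    timepoints. Deltas are differences between consecutive timepoints.
    """
    if not reports:
        raise ValueError("no reports given")
    patients = {r["patient_id"] for r in reports}
    if len(patients) > 1:
        raise ValueError(f"mixed patients in longitudinal summary: {sorted(patients)}")

    rows: dict[str, dict] = {}
    for report in reports:
        quant = report.get("quant") or {}
        instab = (report.get("cnv") or {}).get("instability") or {}
        for tp, entry in quant.items():
            if not isinstance(entry, dict) or entry.get("status") != "computed":
                continue
            rows[tp] = {
                "timepoint": tp,
                "vaf": entry["vaf"],
                "copies_per_ml_plasma_mut": entry.get("copies_per_ml_plasma_mut"),
                "instability": instab.get(tp),
            }
    if len(rows) < 2:
        raise ValueError("need at least two computed timepoints")
    df = pd.DataFrame([rows[tp] for tp in sorted(rows)]).set_index("timepoint")
    for col in ("vaf", "copies_per_ml_plasma_mut", "instability"):
        df[f"delta_{col}"] = df[col].diff()
    return df
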