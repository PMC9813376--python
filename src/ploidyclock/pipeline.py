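"""End-to-end per-sample runs: consensus -> SCNA/WGD -> timing -> report.

The report schema is published as a pydantic model
(:class:`PatientReport`); ``PatientReport.model_json_schema()`` is the
machine-readable contract and every emitted report validates against
it. Reports contain no timestamps so identical inputs + seed produce
byte-identical files.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from pydantic import BaseModel

from . import __version__
from .cn import call_wgd, compute_ploidy, scna_fractions
from .consensus import merge_snv_calls, merge_sv_calls
from .exceptions import PloidyclockError, ValidationError
from .io import read_segments_tsv, read_sv_vcf, read_vcf_minimal
from .timing import SampleMeta, WGDTimingModel

log = logging.getLogger("ploidyclock")


@dataclass
class RunConfig:
    """Inputs and thresholds for one patient-level run."""

    segments: str
    snv_vcfs: list[str] = field(default_factory=list)
    sv_vcfs: list[str] = field(default_factory=list)
    sample_id: Optional[str] = None
    purity: float = 1.0
    age_at_diagnosis: Optional[float] = None
    wgd_fraction: float = 0.5
    polyploid_ploidy: float = 2.5
    min_callers_snv: int = 2
    min_callers_sv: int = 2
    sv_tolerance: int = 100
    bootstrap: int = 1000
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError("purity must be in (0, 1]")
        if not (0.0 < self.wgd_fraction <= 1.0):
            raise ValidationError("wgd_fraction must be in (0, 1]")
        if self.min_callers_snv < 1 or self.min_callers_sv < 1:
            raise ValidationError("min_callers must be >= 1")
        if self.sv_tolerance < 0 or self.bootstrap < 1:
            raise ValidationError("sv_tolerance >= 0 and bootstrap >= 1 required")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


class WGDReportModel(BaseModel):
    n_wgd: int
    fraction_major_ge2: float
    fraction_major_ge4: float
    ploidy: float
    polyploid: bool


class TimingEventModel(BaseModel):
    pi_hat: float
    ci_low: float
    ci_high: float
    years_before_diagnosis: Optional[float] = None
    years_ci_low: Optional[float] = None
    years_ci_high: Optional[float] = None


class TimingReportModel(BaseModel):
    n_wgd: int
    n_bootstrap: int
    level: float
    n_informative: int
    n_pre: int
    n_post: int
    n_mid: Optional[int] = None
    events: list[TimingEventModel]


class PatientReport(BaseModel):
    """Machine-readable per-sample report (the published schema)."""

    version: str
    sample: str
    seed: int
    thresholds: dict[str, float]
    n_snv_input_callsets: int
    n_snv_consensus: int
    n_sv_input_callsets: int
    n_sv_consensus: int
    scna_fractions: dict[str, float]
    ploidy: float
    wgd: WGDReportModel
    timing: Optional[TimingReportModel] = None
    timing_skipped_reason: Optional[str] = None


def run_patient_pipeline(config: RunConfig) -> dict:
    """Run consensus -> SCNA -> WGD -> timing on one sample.

    Returns the validated report as a plain dict; if ``config.out_dir``
    is set, writes ``report.json`` there (removed again on any stage
    failure so no partial outputs survive).
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    report_path = out_dir / "report.json" if out_dir else None
    try:
        return _run(config, report_path)
    except Exception:
        if report_path is not None and report_path.exists():
            report_path.unlink()
        raise


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PloidyclockError as exc:
                raise PloidyclockError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _run(config: RunConfig, report_path: Optional[Path]) -> dict:
    log.info("ploidyclock %s | seed=%d | thresholds: wgd_fraction=%g "
             "min_callers_snv=%d min_callers_sv=%d sv_tolerance=%d bootstrap=%d",
             __version__, config.seed, config.wgd_fraction,
             config.min_callers_snv, config.min_callers_sv,
             config.sv_tolerance, config.bootstrap)

    profiles = _stage("segments")(read_segments_tsv)(
        config.segments, purity=config.purity)
    if config.sample_id is not None:
        if config.sample_id not in profiles:
            raise ValidationError(
                f"sample {config.sample_id!r} not in segment table "
                f"(has {sorted(profiles)})")
        profile = profiles[config.sample_id]
    elif len(profiles) == 1:
        profile = next(iter(profiles.values()))
    else:
        raise ValidationError(
            f"segment table has {len(profiles)} samples; set sample_id")

    callsets = [
        _stage("consensus-snv")(read_vcf_minimal)(p, caller_id=f"caller{i}")
        for i, p in enumerate(config.snv_vcfs)
    ]
    consensus_snvs = []
    if callsets:
        consensus_snvs = _stage("consensus-snv")(merge_snv_calls)(
            callsets, min_callers=config.min_callers_snv)
        log.info("SNV consensus: %d/%d unique calls retained",
                 len(consensus_snvs), len({r.key for cs in callsets for r in cs}))

    sv_callsets = [
        _stage("consensus-sv")(read_sv_vcf)(p, caller_id=f"svcaller{i}")
        for i, p in enumerate(config.sv_vcfs)
    ]
    consensus_svs = []
    if sv_callsets:
        consensus_svs = _stage("consensus-sv")(merge_sv_calls)(
            sv_callsets, min_callers=config.min_callers_sv,
            tolerance_bp=config.sv_tolerance)
        log.info("SV consensus: %d clusters retained", len(consensus_svs))

    fractions = _stage("scna")(scna_fractions)(profile)
    wgd = _stage("wgd-call")(call_wgd)(profile, threshold=config.wgd_fraction)
    log.info("WGD call: n_wgd=%d ploidy=%.2f", wgd.n_wgd, wgd.ploidy)

    timing_dict = None
    skipped = None
    if wgd.n_wgd == 0:
        skipped = "no WGD called (n_wgd=0); mutation-clock timing not applicable"
        log.info("timing skipped: %s", skipped)
    elif not consensus_snvs:
        skipped = "no consensus SNVs supplied; nothing to time"
        log.info("timing skipped: %s", skipped)
    else:
        meta = None
        if config.age_at_diagnosis is not None:
            meta = SampleMeta(profile.sample_id, config.age_at_diagnosis,
                              profile.purity)
        model = WGDTimingModel.from_records(
            [c.record for c in consensus_snvs], profile, min(wgd.n_wgd, 2), meta)
        results = _stage("timing")(model.fit)(
            n_bootstrap=config.bootstrap, seed=config.seed)
        timing_dict = results.as_dict()
        log.info("timing: %s", [round(float(p), 3) for p in results.pi])

    report = PatientReport(
        version=__version__,
        sample=profile.sample_id,
        seed=config.seed,
        thresholds={
            "wgd_fraction": config.wgd_fraction,
            "polyploid_ploidy": config.polyploid_ploidy,
            "min_callers_snv": config.min_callers_snv,
            "min_callers_sv": config.min_callers_sv,
            "sv_tolerance": config.sv_tolerance,
            "bootstrap": config.bootstrap,
        },
        n_snv_input_callsets=len(callsets),
        n_snv_consensus=len(consensus_snvs),
        n_sv_input_callsets=len(sv_callsets),
        n_sv_consensus=len(consensus_svs),
        scna_fractions=fractions,
        ploidy=compute_ploidy(profile),
        wgd=WGDReportModel(**wgd.as_dict()),
        timing=TimingReportModel(**timing_dict) if timing_dict else None,
        timing_skipped_reason=skipped,
    )
    payload = report.model_dump()
    if report_path is not None:
        report_path.parent.mkdir(parents=True, exist_ok=True)
        report_path.write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        log.info("report written to %s", report_path)
    return payload


def report_json_schema() -> dict:
    """The JSON schema every report validates against."""
    return PatientReport.model_json_schema()
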