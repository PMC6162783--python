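"""End-to-end study pipeline: quantify -> reliability -> validity.

:class:`StudyConfig` collects every analysis choice (zone factors, TRIMP
weighting, block definition, ICC variant, quartile mode, CI method, alpha,
seed) with defaults reproducing the standard constants of the method: Borg
6-20 RPE, Edwards zone factors 1-5, TRIMP coefficients (0.64, 1.92),
alpha = 0.05, and the two 3-week training blocks (weeks 2-4 vs 6-8).

:func:`run_pipeline` executes the three stages in order on the participant
and session CSVs, writes all artifacts plus a manifest (config hash, seed,
versions, output checksums, every warning raised), and preserves partial
artifacts with the failure point marked if a stage fails. Outputs are
byte-stable for a fixed config and input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .agreement import DEFAULT_BLOCKS, reliability_report
from .cohort import participants_to_frame
from .exceptions import ConfigurationError, HiftLoadError
from .io import read_participants, read_sessions
from .loads import ZoneFactorTable, loads_to_frame, quantify_sessions
from .validity import block_regression, pearson_by_scope, validity_report

__all__ = ["StudyConfig", "run_pipeline"]


@dataclass(frozen=True)
class StudyConfig:
    """Analysis configuration for one pipeline run."""

    participants_csv: str = "participants.csv"
    sessions_csv: str = "sessions.csv"
    zone_factors: ZoneFactorTable = field(default_factory=ZoneFactorTable)
    trimp_weighting: str = "default"
    blocks: dict = field(default_factory=lambda: {
        k: tuple(v) for k, v in DEFAULT_BLOCKS.items()})
    icc_variant: str = "ICC(A,1)"
    quartile_mode: str = "block-local"
    ci_method: str = "bootstrap"
    n_boot: int = 2000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(
                f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.n_boot < 1:
            raise ConfigurationError(
                f"n_boot must be >= 1, got {self.n_boot!r}")
        if self.quartile_mode not in ("block-local", "study-wide"):
            raise ConfigurationError(
                f"quartile_mode must be 'block-local' or 'study-wide', "
                f"got {self.quartile_mode!r}")
        if self.ci_method not in ("bootstrap", "fisher"):
            raise ConfigurationError(
                f"ci_method must be 'bootstrap' or 'fisher', "
                f"got {self.ci_method!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zone_factors"] = {"bands": [list(b) for b in self.zone_factors.bands],
                             "sub50_factor": self.zone_factors.sub50_factor}
        d["blocks"] = {k: list(v) for k, v in self.blocks.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "zone_factors" in data and isinstance(data["zone_factors"], dict):
            zf = data["zone_factors"]
            data["zone_factors"] = ZoneFactorTable(
                bands=tuple(tuple(b) for b in zf["bands"]),
                sub50_factor=zf.get("sub50_factor", 0.0))
        if "blocks" in data:
            data["blocks"] = {k: tuple(v) for k, v in data["blocks"].items()}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config field(s) {sorted(unknown)}")
        return cls(**data)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: StudyConfig, out_dir) -> dict:
    """Run quantify -> reliability -> validity, writing all artifacts.

    Returns the manifest dict (also written to ``manifest.json``). On stage
    failure the manifest records the failure point and the exception is
    re-raised; artifacts from completed stages remain on disk.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"hiftload": __version__},
        "stages": [],
        "outputs": {},
        "warnings": [],
        "status": "ok",
    }

    def finish_stage(name):
        manifest["stages"].append(name)

    caught: list = []
    try:
        with warnings.catch_warnings(record=True) as wlog:
            warnings.simplefilter("always")

            # -- quantify ------------------------------------------------
            participants = read_participants(config.participants_csv)
            sessions = read_sessions(config.sessions_csv)
            records = quantify_sessions(participants, sessions,
                                        factors=config.zone_factors,
                                        weighting=config.trimp_weighting)
            loads = loads_to_frame(records)
            loads_path = out / "loads.csv"
            loads.to_csv(loads_path, index=False)
            finish_stage("quantify")

            # -- reliability ----------------------------------------------
            rel = reliability_report(loads, blocks=config.blocks,
                                     quartile_mode=config.quartile_mode,
                                     icc_variant=config.icc_variant)
            rel_path = out / "reliability.json"
            _json_dump({
                "overall": rel["overall"].to_dict(),
                "per_block": {k: v.to_dict() for k, v in rel["per_block"].items()},
                "quartile_mode": rel["quartile_mode"],
            }, rel_path)
            finish_stage("reliability")

            # -- validity -------------------------------------------------
            entries = pearson_by_scope(loads, participants_to_frame(participants),
                                       alpha=config.alpha)
            regressions = []
            for criterion in ("edwards_tl", "trimp"):
                regressions.extend(block_regression(
                    loads, blocks=config.blocks, criterion=criterion,
                    ci_method=config.ci_method, n_boot=config.n_boot,
                    seed=config.seed))
            table, summary = validity_report(entries, regressions)
            table_path = out / "validity_correlations.csv"
            table.to_csv(table_path, index=False)
            summary_path = out / "validity_regression.json"
            _json_dump(summary, summary_path)
            finish_stage("validity")

        caught = [str(w.message) for w in wlog]
    except HiftLoadError as exc:
        manifest["status"] = "failed"
        stage_names = ["quantify", "reliability", "validity"]
        done = set(manifest["stages"])
        manifest["failed_stage"] = next(s for s in stage_names if s not in done)
        manifest["error"] = str(exc)
        manifest["warnings"] = caught
        _json_dump(manifest, out / "manifest.json")
        raise

    manifest["warnings"] = caught
    for p in sorted(out.glob("*")):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    _json_dump(manifest, out / "manifest.json")
    return manifest
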