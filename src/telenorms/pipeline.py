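"""End-to-end orchestration: simulate → screen → fit → adjust → norms →
(optionally) compare two normative systems; every artifact lands in an
output directory and is listed, with a SHA-256 checksum and the seed, in
a manifest JSON.  Re-running the same config reproduces every file
bit-exactly.

All randomness flows from one global seed through named per-stage
substreams (`numpy.random.SeedSequence(seed, spawn_key)`), so each stage
is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjust import adjust_table, build_grid, descriptive_screen, fit_adjustment
from .cohort import CohortTable, SimulationSpec, amci_patient_spec, study_sample_spec
from .concordance import NormativeSystem, run_comparison
from .fixtures import PUBLISHED_ES_TABLE, published_equations
from .norms import es_thresholds, percentile_table, tolerance_limits
from .simulate import simulate_healthy_cohort, simulate_patient_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

#: stage names, in execution order; also the seed substream labels
STAGES = ("simulate", "screen", "fit", "adjust", "norms", "concordance")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort_csv`` / ``simulate_n`` selects the healthy
    cohort source; the concordance stage runs only when a patient source
    (``patients_csv`` or ``simulate_patients``) is given.
    """

    out_dir: str | Path = "telenorms_out"
    seed: int = 0
    cohort_csv: str | Path | None = None
    simulate_n: int | None = 204
    patients_csv: str | Path | None = None
    simulate_patients: bool = False
    patients_n: int = 100
    tests: list[str] | None = None
    alpha_enter: float = 0.05
    alpha_remove: float = 0.05
    impairment_cutoff: str = "otl"  # Equivalent Score 0 boundary

    def validate(self) -> None:
        if (self.cohort_csv is None) == (self.simulate_n is None):
            raise ValueError(
                "exactly one of cohort_csv / simulate_n must be given"
            )
        for path in (self.cohort_csv, self.patients_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(str(path))
        if self.impairment_cutoff != "otl":
            raise ValueError("only the 'otl' impairment cutoff is supported")

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(STAGES.index(stage),))
        return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = {k: str(v) for k, v in dataclasses.asdict(config).items()}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass
class _Manifest:
    seed: int
    config_hash: str
    version: str = __version__
    stages: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "stages": self.stages,
            "artifacts": self.artifacts,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the normative pipeline; returns the manifest dict.

    Any stage failure marks that stage ``failed`` in the manifest and
    skips the stages after it.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(seed=config.seed, config_hash=_config_hash(config))
    manifest_path = out / "manifest.json"

    def fail(stage: str, err: Exception) -> dict:
        logger.error("stage %s failed: %s", stage, err)
        manifest.stages[stage] = f"failed: {err}"
        for later in STAGES[STAGES.index(stage) + 1:]:
            manifest.stages[later] = "skipped"
        manifest.write(manifest_path)
        return json.loads(manifest_path.read_text())

    # -- simulate ---------------------------------------------------------
    try:
        if config.cohort_csv is not None:
            cohort = CohortTable.from_csv(config.cohort_csv)
            manifest.stages["simulate"] = "skipped (cohort loaded from CSV)"
        else:
            spec = study_sample_spec(
                n=config.simulate_n, seed=config.stage_seed("simulate")
            )
            cohort = simulate_healthy_cohort(spec)
            path = out / "cohort.csv"
            cohort.to_csv(path)
            spec.to_json(out / "cohort_spec.json")
            manifest.record("cohort", path)
            manifest.record("cohort_spec", out / "cohort_spec.json")
            manifest.stages["simulate"] = "ok"

        patients = None
        if config.patients_csv is not None:
            patients = CohortTable.from_csv(config.patients_csv)
        elif config.simulate_patients:
            pspec = amci_patient_spec(
                n=config.patients_n, seed=config.stage_seed("simulate")
            )
            patients = simulate_patient_cohort(pspec)
            path = out / "patients.csv"
            patients.to_csv(path)
            pspec.to_json(out / "patients_spec.json")
            manifest.record("patients", path)
            manifest.record("patients_spec", out / "patients_spec.json")
    except Exception as err:  # noqa: BLE001 - stage boundary
        return fail("simulate", err)

    tests = config.tests or cohort.tests

    # -- descriptive screen ----------------------------------------------
    try:
        screen = descriptive_screen(cohort)
        screen["descriptives"].to_csv(out / "descriptives.csv",
                                      lineterminator="\n")
        screen["correlations"].round(6).to_csv(out / "correlations.csv",
                                               lineterminator="\n")
        manifest.record("descriptives", out / "descriptives.csv")
        manifest.record("correlations", out / "correlations.csv")
        manifest.stages["screen"] = "ok"
    except Exception as err:  # noqa: BLE001
        return fail("screen", err)

    # -- fit + grids ------------------------------------------------------
    equations = {}
    try:
        for test in tests:
            eq = fit_adjustment(cohort, test, config.alpha_enter,
                                config.alpha_remove)
            equations[test] = eq
            eq.to_json(out / f"equation_{test}.json")
            manifest.record(f"equation_{test}", out / f"equation_{test}.json")
            if eq.terms:
                grid = build_grid(eq)
                grid.to_csv(out / f"grid_{test}.csv")
                manifest.record(f"grid_{test}", out / f"grid_{test}.csv")
        manifest.stages["fit"] = "ok"
    except Exception as err:  # noqa: BLE001
        return fail("fit", err)

    # -- adjusted scores --------------------------------------------------
    try:
        adjusted = pd.DataFrame({"id": cohort.df["id"]})
        for test in tests:
            adjusted[test] = adjust_table(equations[test], cohort)
        adjusted.to_csv(out / "adjusted.csv", index=False, lineterminator="\n")
        manifest.record("adjusted", out / "adjusted.csv")
        manifest.stages["adjust"] = "ok"
    except Exception as err:  # noqa: BLE001
        return fail("adjust", err)

    # -- normative tables -------------------------------------------------
    thresholds = {}
    try:
        pct_rows = []
        for test in tests:
            x = adjusted[test].to_numpy()
            limits = tolerance_limits(x)
            th = es_thresholds(x, limits, test=test)
            thresholds[test] = th
            th.to_json(out / f"es_{test}.json")
            manifest.record(f"es_{test}", out / f"es_{test}.json")
            pct = percentile_table(x, test=test)
            row = {"test": test}
            row.update(pct.rounded(1))
            pct_rows.append(row)
        pd.DataFrame(pct_rows).to_csv(out / "percentiles.csv", index=False,
                                      lineterminator="\n")
        manifest.record("percentiles", out / "percentiles.csv")
        manifest.stages["norms"] = "ok"
    except Exception as err:  # noqa: BLE001
        return fail("norms", err)

    # -- concordance (optional) -------------------------------------------
    if patients is None:
        manifest.stages["concordance"] = "skipped"
    else:
        try:
            new_systems = {
                t: NormativeSystem("remote", equations[t],
                                   thresholds=thresholds[t])
                for t in tests
            }
            ref_eqs = published_equations()
            ref_systems = {
                t: NormativeSystem("published", ref_eqs[t],
                                   cutoff=PUBLISHED_ES_TABLE[t]["otl"])
                for t in tests if t in ref_eqs
            }
            results = run_comparison(
                patients, new_systems, ref_systems, tests,
                seed=config.stage_seed("concordance"),
            )
            metrics = {t: r.stats.to_dict() for t, r in results.items()}
            (out / "metrics.json").write_text(
                json.dumps(metrics, indent=2, sort_keys=True) + "\n"
            )
            manifest.record("metrics", out / "metrics.json")
            cm_rows = []
            roc_frames = []
            for t, r in results.items():
                cm_rows.append({"test": t, "a": r.confusion.a,
                                "b": r.confusion.b, "c": r.confusion.c,
                                "d": r.confusion.d})
                roc = r.roc.copy()
                roc.insert(0, "test", t)
                roc_frames.append(roc)
            pd.DataFrame(cm_rows).to_csv(out / "confusion.csv", index=False,
                                         lineterminator="\n")
            pd.concat(roc_frames).to_csv(out / "roc.csv", index=False,
                                         lineterminator="\n")
            manifest.record("confusion", out / "confusion.csv")
            manifest.record("roc", out / "roc.csv")
            manifest.stages["concordance"] = "ok"
        except Exception as err:  # noqa: BLE001
            return fail("concordance", err)

    manifest.write(manifest_path)
    return json.loads(manifest_path.read_text())
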