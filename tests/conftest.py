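"""Shared fixtures: forged models and an audited truth cohort.

Everything is generated programmatically at test time; the heavyweight
pieces (the 50-model truth cohort and its audit) are session-scoped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pytest

from repeataudit import (
    FeatureInjection, ScoreTable3D1D, SolenoidSpec, build_coil, build_helix,
    build_solenoid, default_truth_specs, forge_truth_cohort, make_unit, tandem,
)

COHORT_SEED = 11


@pytest.fixture(scope="session")
def truth_dir(tmp_path_factory) -> Path:
    """Default 50-model forged cohort with truth labels on disk."""
    out = tmp_path_factory.mktemp("truth_cohort")
    forge_truth_cohort(default_truth_specs(COHORT_SEED), out, seed=COHORT_SEED)
    return out


@pytest.fixture(scope="session")
def truth_records(truth_dir) -> list[dict]:
    with open(truth_dir / "truth.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def constant_table_path(tmp_path_factory) -> Path:
    """A flat 3D/1D table so audits are independent of the shipped scores."""
    path = tmp_path_factory.mktemp("tables") / "constant_0.3.tsv"
    ScoreTable3D1D.constant(0.3).to_tsv(path)
    return path


@pytest.fixture(scope="session")
def audited_report(truth_dir, constant_table_path, tmp_path_factory):
    """(report_path, DataFrame) for one audit pass over the truth cohort."""
    import pandas as pd
    from click.testing import CliRunner

    from repeataudit.cohort_cli import main

    out = tmp_path_factory.mktemp("audit") / "report.tsv"
    result = CliRunner().invoke(main, [
        "audit", "--structures", str(truth_dir),
        "--manifest", str(truth_dir / "manifest.tsv"),
        "--score-table", str(constant_table_path),
        "--out-report", str(out),
    ])
    assert result.exit_code == 0, result.output
    return out, pd.read_csv(out, sep="\t", comment="#")


@pytest.fixture(scope="session")
def solenoid12():
    """A clean 12-residue-unit, 10-rung β-pool solenoid."""
    unit = make_unit(12, "beta", seed=3)
    return build_solenoid(SolenoidSpec(sequence=tandem(unit, 10)))


@pytest.fixture(scope="session")
def stack_solenoid():
    """Same geometry with an uncompensated glutamate stack at position 0."""
    unit = make_unit(12, "beta", seed=3)
    return build_solenoid(SolenoidSpec(
        sequence=tandem(unit, 10),
        injections=[FeatureInjection("charged_stack", 0, "E")]))


@pytest.fixture(scope="session")
def helix100():
    return build_helix("A" * 100)


@pytest.fixture(scope="session")
def coil60():
    return build_coil("G" * 60, seed=5)
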