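"""Shared fixtures: one default synthetic cohort reused across the suite."""

from __future__ import annotations

import pytest

from degratrack import signal_scan, synthetic_data


@pytest.fixture(scope="session")
def default_config() -> synthetic_data.CohortConfig:
    return synthetic_data.CohortConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(default_config) -> synthetic_data.Cohort:
    return synthetic_data.build_cohort(default_config)


@pytest.fixture(scope="session")
def extended_precursors(cohort):
    return cohort.extended_precursors(50)


@pytest.fixture(scope="session")
def pooled_library(cohort):
    return synthetic_data.simulate_degradome(cohort)


@pytest.fixture(scope="session")
def pooled_scan(pooled_library, extended_precursors) -> signal_scan.ScanResult:
    return signal_scan.scan_library(pooled_library, extended_precursors)


@pytest.fixture(scope="session")
def tissue_scans(cohort, extended_precursors) -> dict[str, signal_scan.ScanResult]:
    out = {}
    for tissue in cohort.config.tissues:
        lib = synthetic_data.simulate_degradome(cohort, tissue=tissue)
        out[tissue] = signal_scan.scan_library(lib, extended_precursors)
    return out
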