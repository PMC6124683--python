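"""End-to-end convenience chain: generate -> process -> analyze."""

from __future__ import annotations

from .cohort import Cohort, CohortSpec, generate_cohort
from .hut import CohortResult, analyze_cohort
from .mbll import ConcentrationSeries, process_recording


def process_cohort(cohort: Cohort) -> list[tuple]:
    """MBLL-process every subject; returns (SubjectRecord,
    ConcentrationSeries, (ref_time, ref_values)) triples for analysis."""
    triples = []
    for s in cohort.subjects:
        conc = process_recording(s.recording, path=cohort.spec.path)
        triples.append((s.record, conc, (s.reference_time_s, s.reference_pct)))
    return triples


def run_study(spec: CohortSpec | None = None, alpha: float = 0.01,
              ) -> tuple[Cohort, list[tuple], CohortResult]:
    """Generate the default synthetic cohort, run the Beer-Lambert
    inversion on every subject and compute the tilt-table statistics."""
    spec = spec or CohortSpec()
    cohort = generate_cohort(spec)
    processed = process_cohort(cohort)
    result = analyze_cohort(processed, proto=spec.protocol, alpha=alpha)
    return cohort, processed, result
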