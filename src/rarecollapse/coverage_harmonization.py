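"""Case/control coverage harmonization.

Exome capture differences between cohorts make some sites well covered in
one group and poorly covered in the other; variants at such sites produce
spurious case-control differences.  For every candidate site we compute
the fraction of cases and of controls with >=10x coverage and drop the
site when the two fractions differ by more than ``max_diff`` (default
11.97%).  Comparison uses exact rational arithmetic so that a difference
of exactly the threshold is retained (the rule is strict ">").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

from .cohort_io import CoverageTable, SampleManifest

logger = logging.getLogger("rarecollapse")

DEFAULT_MAX_DIFF = 0.1197


@dataclass
class SiteCoverageSummary:
    site: tuple[str, int]
    frac_cases_10x: Fraction
    frac_controls_10x: Fraction
    pruned: bool = False


def coverage_fractions(
    coverage: CoverageTable,
    manifest: SampleManifest,
    sites,
) -> list[SiteCoverageSummary]:
    """Per-site fractions of cases and controls with >=10x coverage."""
    cases = manifest.case_ids
    controls = manifest.control_ids
    if not cases or not controls:
        raise ValueError("both case and control groups must be non-empty")
    out = []
    for chrom, pos in sites:
        fc = Fraction(coverage.covered_count(chrom, pos, cases), len(cases))
        fk = Fraction(coverage.covered_count(chrom, pos, controls), len(controls))
        out.append(SiteCoverageSummary((chrom, pos), fc, fk))
    return out


def prune_imbalanced_sites(
    summaries: list[SiteCoverageSummary],
    max_diff: float = DEFAULT_MAX_DIFF,
) -> set[tuple[str, int]]:
    """Retain sites whose case/control coverage gap is <= max_diff.

    Marks ``pruned`` in place and returns the retained site keys.
    """
    threshold = Fraction(str(max_diff))
    retained = set()
    for s in summaries:
        s.pruned = abs(s.frac_cases_10x - s.frac_controls_10x) > threshold
        if not s.pruned:
            retained.add(s.site)
    n_pruned = len(summaries) - len(retained)
    if summaries:
        logger.info(
            "coverage harmonization pruned %d/%d sites (%.2f%%)",
            n_pruned, len(summaries), 100.0 * n_pruned / len(summaries),
        )
    return retained


def harmonize(
    coverage: CoverageTable,
    manifest: SampleManifest,
    sites,
    max_diff: float = DEFAULT_MAX_DIFF,
) -> tuple[set[tuple[str, int]], list[SiteCoverageSummary]]:
    """Convenience wrapper: fractions then pruning."""
    summaries = coverage_fractions(coverage, manifest, sites)
    retained = prune_imbalanced_sites(summaries, max_diff=max_diff)
    return retained, summaries
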