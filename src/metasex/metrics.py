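"""Normalized sex-chromosome coverage statistics.

Two statistics summarize the dosage signal in a per-chromosome count table:

* ``rx`` — the mean, over autosomes, of homogametic-chromosome coverage
  divided by that autosome's coverage.  With coverage measured as mapped
  reads per effective base pair, an XX (or ZZ) individual sits near 1.0 and
  an XY (or ZW) individual near 0.5, because the homogametic chromosome is
  present in two vs one copies against a diploid autosomal background.
* ``ry`` — the fraction of sex-chromosome reads on the heterogametic
  chromosome, Y/(X+Y) (W/(Z+W) in ZW systems); near 0 for the homogametic
  karyotype and positive for the heterogametic one.

The names are role-based: in a ZW genome ``rx`` is Z-versus-autosomes and
``ry`` is W/(Z+W).  Both are undefined (``None``) rather than raising when
the data cannot support them — a zero denominator, or too few autosomes
with any coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GenomeSpec
from .idxstats import IdxstatsTable, total_host_reads

__all__ = ["SexMetrics", "coverage", "compute_rx", "compute_ry", "compute_metrics",
           "DEFAULT_MIN_AUTOSOMES"]

#: Minimum number of autosomes with non-zero coverage for rx to be defined.
#: At very low read depth some autosomes receive no reads; those are skipped
#: and the mean taken over the rest, down to this floor.
DEFAULT_MIN_AUTOSOMES = 5


@dataclass(frozen=True)
class SexMetrics:
    """The (rx, ry) pair plus bookkeeping for one sample."""

    rx: float | None
    ry: float | None
    total_host_reads: int
    n_autosomes_used: int

    @property
    def defined(self) -> bool:
        return self.rx is not None and self.ry is not None


def coverage(mapped: int, effective_length: int) -> float:
    """Mapped reads per effective base pair."""
    if effective_length < 1:
        raise ValueError("effective_length must be >= 1")
    return mapped / effective_length


def compute_rx(
    table: IdxstatsTable, spec: GenomeSpec, min_autosomes: int = DEFAULT_MIN_AUTOSOMES
) -> tuple[float | None, int]:
    """Mean homogametic-vs-autosome coverage ratio.

    Autosomes with zero mapped reads are skipped (their ratio is a division
    by zero, not evidence); returns ``(None, n_used)`` when fewer than
    ``min_autosomes`` autosomes remain.  Zero homogametic coverage yields a
    defined rx of 0.0 — a heterogametic individual with no X reads at tiny
    depth is real data, not a degenerate case.
    """
    homo = spec.homogametic
    homo_cov = coverage(table.mapped(homo.id), homo.effective_length)
    ratios = []
    for aut in spec.autosomes:
        mapped = table.mapped(aut.id)
        if mapped == 0:
            continue
        ratios.append(homo_cov / coverage(mapped, aut.effective_length))
    if len(ratios) < min_autosomes:
        return None, len(ratios)
    return sum(ratios) / len(ratios), len(ratios)


def compute_ry(table: IdxstatsTable, spec: GenomeSpec) -> float | None:
    """Heterogametic fraction of sex-chromosome reads; ``None`` if no such reads."""
    x_reads = table.mapped(spec.homogametic.id)
    y_reads = table.mapped(spec.heterogametic.id)
    denom = x_reads + y_reads
    if denom == 0:
        return None
    return y_reads / denom


def compute_metrics(
    table: IdxstatsTable, spec: GenomeSpec, min_autosomes: int = DEFAULT_MIN_AUTOSOMES
) -> SexMetrics:
    rx, n_used = compute_rx(table, spec, min_autosomes=min_autosomes)
    return SexMetrics(
        rx=rx,
        ry=compute_ry(table, spec),
        total_host_reads=total_host_reads(table, spec),
        n_autosomes_used=n_used,
    )
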