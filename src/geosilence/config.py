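"""Analysis configuration: the thresholds that define the silencing pipeline.

All of the biologically meaningful knobs live in :class:`AnalysisConfig` so
that a run is fully described by one object: the silencing fraction (how much
lower than the cluster mean a transcript count must be to call a gene
silenced), the minimum run length that makes a stretch of consecutive
silenced genes a "geographical silencing event", the per-cell burden
thresholds that separate high-burden cells from the low extreme, the
prevalence cut used to pick recurrently silenced genes, and the set of
somatic chromosomes the analysis is restricted to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

__all__ = [
    "AnalysisConfig",
    "MOUSE_SOMATIC_CHROMOSOMES",
    "HUMAN_SOMATIC_CHROMOSOMES",
    "somatic_chromosomes",
]

#: Mouse autosomes (the sex chromosomes and the mitochondrial genome are
#: excluded from the geography analysis).
MOUSE_SOMATIC_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20))

#: Human autosomes.
HUMAN_SOMATIC_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

_EXCLUDED_CHROMOSOMES = {"X", "Y", "MT", "M"}

_NORMALIZATIONS = ("raw", "depth_scaled")
_EXPRESSED_RULES = ("cluster_mean_positive", "min_cells")


def somatic_chromosomes(species: str) -> tuple[str, ...]:
    """Return the default somatic (autosomal) chromosome names for a species."""
    key = species.lower()
    if key in ("mouse", "mm", "mus_musculus"):
        return MOUSE_SOMATIC_CHROMOSOMES
    if key in ("human", "hs", "homo_sapiens"):
        return HUMAN_SOMATIC_CHROMOSOMES
    raise ValueError(f"unknown species {species!r}; expected 'mouse' or 'human'")


def normalize_chromosome_name(name: str) -> str:
    """Strip a leading ``chr`` prefix and upper-case the residue.

    Mouse and human annotation dialects disagree about the ``chr`` prefix;
    comparisons throughout the package are made on the stripped form.
    """
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name.upper() if name.upper() in _EXCLUDED_CHROMOSOMES else name


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and switches for the silencing analysis.

    Parameters
    ----------
    silencing_fraction
        Fraction reduction θ relative to the cluster mean that defines a
        silenced gene. The default 0.5 encodes hemi-allelic silencing: a
        gene is silenced in a cell when its (normalized) count is at most
        ``(1 - θ)`` times the mean of the cells in its cluster.
    min_run_length
        Minimum number of consecutive silenced genes, in genome order, for
        a run to count as a geographical silencing event (default 10).
    high_burden_threshold
        A cell is "high burden" when its number of qualifying events is
        strictly greater than this (default 150).
    low_burden_threshold
        A cell is "low burden" when its event count is strictly below this
        (default 25). Cells between the two thresholds are intermediate.
    prevalence_threshold
        A gene is recurrently silenced when it is silenced in strictly more
        than this fraction of the cells in which it was evaluated
        (default 0.2).
    somatic_chromosomes
        Chromosome names retained for the geography analysis; X, Y and MT
        are excluded by construction.
    normalization
        ``raw`` (counts as loaded, the literal reading of the silencing
        definition) or ``depth_scaled`` (per-cell total scaled to the
        median total; recommended when sequencing depth varies).
    expressed_rule
        ``cluster_mean_positive``: a gene is evaluated in a cluster when
        its cluster mean is > 0. ``min_cells``: evaluated when detected in
        at least ``min_cells`` cells of the cluster.
    min_cells
        Detection threshold used by the ``min_cells`` rule.
    leave_one_out
        When True the evaluated cell is excluded from its own cluster mean.
    random_seed
        Seed for any stochastic step downstream (e.g., permutations).
    """

    silencing_fraction: float = 0.5
    min_run_length: int = 10
    high_burden_threshold: int = 150
    low_burden_threshold: int = 25
    prevalence_threshold: float = 0.2
    somatic_chromosomes: tuple[str, ...] = MOUSE_SOMATIC_CHROMOSOMES
    normalization: str = "raw"
    expressed_rule: str = "cluster_mean_positive"
    min_cells: int = 3
    leave_one_out: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.silencing_fraction < 1.0:
            raise ValueError("silencing_fraction must lie in (0, 1)")
        if self.min_run_length < 1:
            raise ValueError("min_run_length must be >= 1")
        if self.low_burden_threshold >= self.high_burden_threshold:
            raise ValueError("low_burden_threshold must be < high_burden_threshold")
        if not 0.0 < self.prevalence_threshold < 1.0:
            raise ValueError("prevalence_threshold must lie in (0, 1)")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")
        if self.expressed_rule not in _EXPRESSED_RULES:
            raise ValueError(f"expressed_rule must be one of {_EXPRESSED_RULES}")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        cleaned = tuple(
            normalize_chromosome_name(c) for c in self.somatic_chromosomes
        )
        bad = [c for c in cleaned if c in _EXCLUDED_CHROMOSOMES]
        if bad:
            raise ValueError(
                f"somatic_chromosomes may not include sex/mitochondrial "
                f"chromosomes: {sorted(set(bad))}"
            )
        object.__setattr__(self, "somatic_chromosomes", cleaned)

    def with_(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    # -- flat key=value round-trip -------------------------------------

    def to_file(self, path: str | Path) -> None:
        """Write the config as a flat ``key=value`` text file."""
        lines = []
        for key, value in self.__dict__.items():
            if isinstance(value, tuple):
                value = ",".join(value)
            lines.append(f"{key}={value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a config previously written by :meth:`to_file`."""
        kwargs: dict[str, object] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key == "somatic_chromosomes":
                kwargs[key] = tuple(v for v in value.split(",") if v)
            elif key in ("silencing_fraction", "prevalence_threshold"):
                kwargs[key] = float(value)
            elif key in ("normalization", "expressed_rule"):
                kwargs[key] = value
            elif key == "leave_one_out":
                kwargs[key] = value.lower() in ("true", "1", "yes")
            else:
                kwargs[key] = int(value)
        return cls(**kwargs)
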