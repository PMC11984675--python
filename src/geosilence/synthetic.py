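"""Synthetic cohorts and ion-count images with ground truth.

The scRNA-seq generator emulates a two-arm (control vs. senescent) study
in which senescence manifests as geographically clustered hemi-allelic
silencing: contiguous chromosomal segments whose genes lose half of their
transcript output. Counts follow a negative-binomial model with per-gene
log-normal baseline means and per-cell log-normal depth factors
(variance μ + μ²/k). Each cell receives a number of injected silenced
segments drawn per condition; senescent cells additionally carry a
heavy-tail subpopulation with an extreme segment burden, mirroring the
observation that most cells show few silencing events while a tail of
cells carries an extreme burden. Everything injected is recorded as
ground truth, so detection sensitivity and burden recovery are measurable.

The imaging generator builds MIMS-style ion-count planes for a single cell
with a nuclear ellipse containing optional DNA-dense globules that are
¹³C- and ³¹P-rich but devoid of ¹⁵N labeling, plus an optional condensed
lamina ring; pixel counts are Poisson around region-specific expectations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountDataset
from .mims import R13C_NATURAL, R15N_NATURAL

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "generate_annotation",
    "generate_cohort",
    "segment_detection_sensitivity",
    "burden_recovery_correlation",
    "IonImageSpec",
    "generate_ion_images",
    "write_ion_images",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic two-arm scRNA-seq cohort.

    Defaults describe the study conditions the package is tested under:
    a 19-autosome mouse-like genome, negative-binomial counts, hemi-allelic
    (50%) reduction within injected segments of 12 consecutive genes, a low
    segment burden in control cells, a higher mean burden in senescent
    cells and a heavy-tail senescent subpopulation with an extreme burden.
    """

    n_chromosomes: int = 19
    genes_per_chromosome: int = 1000
    n_cells_control: int = 500
    n_cells_senescent: int = 500
    #: per-gene baseline NB means are log-normal: exp(N(log_mean, log_sd)).
    baseline_log_mean: float = 0.3
    baseline_log_sd: float = 0.3
    #: NB dispersion k, variance = μ + μ²/k.
    dispersion: float = 10.0
    #: per-cell depth factors are log-normal with this sd (unit mean).
    depth_factor_sd: float = 0.45
    #: injected segment lengths: "fixed" (length L*) or "geometric" (mean 1/p).
    segment_length_mode: str = "fixed"
    segment_length: int = 12
    geometric_p: float = 0.1
    #: fractional reduction applied to segment genes (0.5 = hemi-allelic).
    segment_reduction: float = 0.5
    #: mean injected segments per cell, per condition.
    lambda_control: float = 1.0
    lambda_senescent: float = 60.0
    #: fraction of senescent cells in the heavy-tail subpopulation and the
    #: extra mean burden they carry.
    tail_fraction: float = 0.2
    lambda_tail: float = 1500.0
    #: global transcription factor applied to heavy-tail cells' depth,
    #: emulating the overall reduction in RNA synthesis of deep senescence.
    tail_depth_factor: float = 0.85
    #: cluster labels: "condition" copies the condition labels; "single"
    #: puts every cell in one cluster (for exchangeable-arm null studies).
    cluster_mode: str = "condition"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("genome dimensions must be positive")
        if min(self.n_cells_control, self.n_cells_senescent) < 2:
            raise ValueError("each arm needs at least 2 cells")
        if not 0.0 < self.segment_reduction <= 1.0:
            raise ValueError("segment_reduction must lie in (0, 1]")
        if self.lambda_control < 0 or self.lambda_senescent < self.lambda_control:
            raise ValueError("need lambda_senescent >= lambda_control >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.segment_length_mode not in ("fixed", "geometric"):
            raise ValueError("segment_length_mode must be 'fixed' or 'geometric'")
        if self.cluster_mode not in ("condition", "single"):
            raise ValueError("cluster_mode must be 'condition' or 'single'")
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise ValueError("tail_fraction must lie in [0, 1]")
        if not 0.0 < self.tail_depth_factor <= 1.0:
            raise ValueError("tail_depth_factor must lie in (0, 1]")

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome

    @property
    def n_cells(self) -> int:
        return self.n_cells_control + self.n_cells_senescent

    def with_(self, **kwargs) -> "SimulationSpec":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Everything the generator injected, for parameter recovery.

    ``segments`` has one row per injected segment (cell_id, chromosome,
    start_index within the chromosome's gene order, length);
    ``segment_counts`` is the per-cell injected-segment count and
    ``silenced_flags`` the per-cell per-gene injected-silencing indicator.
    """

    segments: pd.DataFrame
    segment_counts: pd.Series
    silenced_flags: np.ndarray

    def validate(self, spec: SimulationSpec) -> None:
        """Exhaustively check segment bounds and per-cell non-overlap."""
        seg = self.segments
        if len(seg) == 0:
            return
        if (seg["start_index"] < 0).any():
            raise AssertionError("segment start below chromosome start")
        if (seg["start_index"] + seg["length"] > spec.genes_per_chromosome).any():
            raise AssertionError("segment exceeds chromosome bounds")
        for (_, _), group in seg.groupby(["cell_id", "chromosome"], observed=True):
            ordered = group.sort_values("start_index")
            ends = ordered["start_index"] + ordered["length"]
            if (ordered["start_index"].to_numpy()[1:] < ends.to_numpy()[:-1]).any():
                raise AssertionError("overlapping segments within one cell")

    def write(self, path) -> None:
        self.segments.to_csv(path, sep="\t", index=False)


def generate_annotation(spec: SimulationSpec) -> pd.DataFrame:
    """Deterministic gene annotation: fixed 10 kb spacing per chromosome.

    Genes are named ``g{chromosome}_{index}`` and laid out at strictly
    increasing starts 10000, 20000, ... within each of the somatic
    chromosomes "1".."n_chromosomes".
    """
    records = []
    for c in range(1, spec.n_chromosomes + 1):
        for i in range(spec.genes_per_chromosome):
            records.append((f"g{c}_{i:04d}", str(c), 10000 * (i + 1), "+"))
    return pd.DataFrame(records, columns=["gene_id", "chromosome", "start", "strand"])


def _sample_segment_length(spec: SimulationSpec, rng: np.random.Generator) -> int:
    if spec.segment_length_mode == "fixed":
        return spec.segment_length
    return int(rng.geometric(spec.geometric_p))


def _uniform_nonoverlapping_starts(
    rng: np.random.Generator, n_genes: int, length: int, k: int
) -> np.ndarray:
    """Uniformly sample k non-overlapping length-``length`` interval starts.

    Standard gap construction: draw k distinct integers from
    ``[0, n_genes - k*length + k)``, sort them, and shift the i-th by
    ``i*(length-1)``; the result is uniform over all non-overlapping
    placements.
    """
    slots = n_genes - k * length + k
    draws = np.sort(rng.choice(slots, size=k, replace=False))
    return draws + np.arange(k) * (length - 1)


def _place_segments(
    spec: SimulationSpec, rng: np.random.Generator, n_segments: int
) -> list[tuple[int, int, int]]:
    """Place non-overlapping (chromosome, start, length) segments for a cell.

    Fixed-length mode assigns segments to chromosomes uniformly (capped at
    each chromosome's capacity, with saturation logged) and samples starts
    with the exact uniform non-overlap construction, so dense burdens up
    to near-full genome coverage stay fast. Variable-length (geometric)
    mode falls back to rejection sampling; over-long draws are rejected
    and resampled.
    """
    n_chrom, n_genes = spec.n_chromosomes, spec.genes_per_chromosome
    placed: list[tuple[int, int, int]] = []
    if n_segments == 0:
        return placed

    if spec.segment_length_mode == "fixed":
        length = spec.segment_length
        if length > n_genes:
            raise ValueError("fixed segment length exceeds chromosome size")
        capacity = n_genes // length
        per_chrom = np.bincount(
            rng.integers(0, n_chrom, n_segments), minlength=n_chrom
        )
        overflow = int(np.maximum(per_chrom - capacity, 0).sum())
        per_chrom = np.minimum(per_chrom, capacity)
        # spill capped segments into chromosomes that still have room
        for _ in range(overflow):
            room = np.flatnonzero(per_chrom < capacity)
            if room.size == 0:
                break
            per_chrom[rng.choice(room)] += 1
        for c in range(n_chrom):
            k = int(per_chrom[c])
            if k == 0:
                continue
            for start in _uniform_nonoverlapping_starts(rng, n_genes, length, k):
                placed.append((c + 1, int(start), length))
    else:
        occupied: dict[int, list[tuple[int, int]]] = {}
        attempts, cap = 0, 50 * n_segments
        while len(placed) < n_segments and attempts < cap:
            attempts += 1
            length = _sample_segment_length(spec, rng)
            if length > n_genes:
                logger.debug("segment longer than chromosome rejected, resampling")
                continue
            chrom = int(rng.integers(1, n_chrom + 1))
            start = int(rng.integers(0, n_genes - length + 1))
            if any(
                start < s + l and s < start + length
                for s, l in occupied.get(chrom, [])
            ):
                continue
            occupied.setdefault(chrom, []).append((start, length))
            placed.append((chrom, start, length))
    if len(placed) < n_segments:
        logger.warning(
            "placed %d of %d requested segments (genome saturated)",
            len(placed),
            n_segments,
        )
    return placed


def generate_cohort(
    spec: SimulationSpec, annotation: pd.DataFrame | None = None
) -> tuple[CountDataset, GroundTruth]:
    """Simulate a control + senescent cohort with injected silenced segments.

    Baseline counts are NB(depth_i × mean_g, k); for every injected segment
    the affected genes' means are multiplied by (1 − r) before sampling.
    Cluster labels equal the condition labels (real clustering is an
    upstream, external step). Returns the dataset together with the ground
    truth of every injected segment.
    """
    if annotation is None:
        annotation = generate_annotation(spec)
    if len(annotation) != spec.n_genes:
        raise ValueError("annotation does not match spec dimensions")
    rng = np.random.default_rng(spec.seed)
    n_cells, n_genes = spec.n_cells, spec.n_genes

    gene_means = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, n_genes)
    # unit-mean log-normal depth factors
    sd = spec.depth_factor_sd
    depth = rng.lognormal(-0.5 * sd**2, sd, n_cells) if sd > 0 else np.ones(n_cells)

    conditions = np.array(
        ["control"] * spec.n_cells_control + ["senescent"] * spec.n_cells_senescent
    )
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]

    lam = np.where(
        conditions == "control", spec.lambda_control, spec.lambda_senescent
    ).astype(float)
    in_tail = (conditions == "senescent") & (
        rng.random(n_cells) < spec.tail_fraction
    )
    n_segments = rng.poisson(lam)
    n_segments[in_tail] += rng.poisson(spec.lambda_tail, int(in_tail.sum()))
    # deep-senescent cells globally transcribe less
    depth = depth * np.where(in_tail, spec.tail_depth_factor, 1.0)

    reduction = np.ones((n_cells, n_genes))
    silenced_flags = np.zeros((n_cells, n_genes), dtype=bool)
    segment_records = []
    for i in range(n_cells):
        for chrom, start, length in _place_segments(spec, rng, int(n_segments[i])):
            lo = (chrom - 1) * spec.genes_per_chromosome + start
            reduction[i, lo : lo + length] *= 1.0 - spec.segment_reduction
            silenced_flags[i, lo : lo + length] = True
            segment_records.append((cell_ids[i], str(chrom), start, length))

    # sample counts in cell blocks to bound peak memory on large cohorts
    shape = spec.dispersion
    blocks = []
    block_size = max(1, min(n_cells, 64_000_000 // max(n_genes, 1)))
    for lo in range(0, n_cells, block_size):
        hi = min(lo + block_size, n_cells)
        mean = depth[lo:hi, None] * gene_means[None, :] * reduction[lo:hi]
        blocks.append(
            sp.csr_matrix(rng.poisson(rng.gamma(shape, mean / shape)))
        )
    counts = sp.vstack(blocks, format="csr")

    segments = pd.DataFrame(
        segment_records, columns=["cell_id", "chromosome", "start_index", "length"]
    )
    segment_counts = pd.Series(
        segments.groupby("cell_id", observed=True).size()
        .reindex(cell_ids)
        .fillna(0)
        .astype(int),
        name="n_segments",
    )
    truth = GroundTruth(
        segments=segments,
        segment_counts=segment_counts,
        silenced_flags=silenced_flags,
    )
    truth.validate(spec)

    meta = pd.DataFrame(
        {
            "condition": conditions,
            "cluster": conditions
            if spec.cluster_mode == "condition"
            else np.repeat("all", n_cells),
        },
        index=pd.Index(cell_ids, name="barcode"),
    )
    dataset = CountDataset(
        counts=counts.astype(np.int64),
        cell_ids=cell_ids,
        gene_ids=annotation["gene_id"].tolist(),
        cell_meta=meta,
    )
    dataset.validate()
    return dataset, truth


def segment_detection_sensitivity(
    truth: GroundTruth,
    run_events: pd.DataFrame,
    annotation: pd.DataFrame,
    min_length: int = 10,
) -> float:
    """Fraction of injected segments overlapped by a detected ≥ L run.

    A segment counts as detected when the same cell carries a run event of
    length ≥ ``min_length`` on the same chromosome whose gene span (in
    within-chromosome annotation order) overlaps the injected interval.
    """
    if len(truth.segments) == 0:
        return float("nan")
    position = (
        annotation.sort_values(["chromosome", "start", "gene_id"], kind="mergesort")
        .groupby("chromosome", observed=True)
        .cumcount()
    )
    pos_of = dict(zip(annotation["gene_id"], position))
    qualifying = run_events[run_events["length"] >= min_length]
    runs_by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for row in qualifying.itertuples(index=False):
        interval = (pos_of[row.first_gene], pos_of[row.last_gene])
        runs_by_key.setdefault((row.cell_id, row.chromosome), []).append(interval)
    detected = 0
    for seg in truth.segments.itertuples(index=False):
        lo, hi = seg.start_index, seg.start_index + seg.length - 1
        for a, b in runs_by_key.get((seg.cell_id, seg.chromosome), []):
            if a <= hi and lo <= b:
                detected += 1
                break
    return detected / len(truth.segments)


def burden_recovery_correlation(
    truth: GroundTruth, burden_records: pd.DataFrame
) -> float:
    """Spearman correlation of detected burden vs. injected segment count."""
    import scipy.stats

    detected = burden_records["n_events"].reindex(truth.segment_counts.index)
    return float(
        scipy.stats.spearmanr(truth.segment_counts.to_numpy(), detected.to_numpy()).statistic
    )


# ---------------------------------------------------------------------------
# Synthetic MIMS ion images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonImageSpec:
    """Region-wise expected counts and enrichments for the image generator.

    Expected major-isotope counts per pixel are set high enough that the
    minor/major ratio is measurable everywhere; enrichments are in % above
    natural background. Globules are ¹³C- and ³¹P-rich and ¹⁵N-devoid;
    the optional lamina ring shares the globules' condensed-DNA makeup.
    """

    c12_counts: tuple[float, float, float] = (2000.0, 5000.0, 8000.0)  # bg, cyto, nucleus
    cn_counts: tuple[float, float, float] = (400.0, 4000.0, 8000.0)
    p_counts: tuple[float, float, float] = (60.0, 400.0, 2500.0)
    s_counts: tuple[float, float, float] = (150.0, 2000.0, 1500.0)
    c13_enrichment: tuple[float, float, float] = (0.0, 0.0, 300.0)
    n15_enrichment: tuple[float, float, float] = (0.0, 60.0, 150.0)
    globule_c13_enrichment: float = 800.0
    globule_n15_enrichment: float = 0.0
    globule_p_counts: float = 6000.0
    globule_cn_counts: float = 9000.0
    lamina_c13_enrichment: float = 700.0
    lamina_n15_enrichment: float = 20.0
    lamina_p_counts: float = 5000.0
    pixel_size_nm: float = 100.0


def _ellipse_mask(height, width, center, radii) -> np.ndarray:
    rows, cols = np.ogrid[:height, :width]
    cy, cx = center
    ry, rx = radii
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


def generate_ion_images(
    width: int = 128,
    height: int = 128,
    n_globules: int = 3,
    globule_radius_px: int = 5,
    nuclear_ellipse: tuple[float, float, float, float] | None = None,
    spec: IonImageSpec | None = None,
    lamina_ring: bool = False,
    seed: int = 0,
    max_placement_tries: int = 1000,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Generate Poisson ion-count planes with ground-truth masks.

    Returns ``(planes, truth)``: planes for ``12C``, ``13C``, ``12C14N``,
    ``12C15N``, ``31P`` and ``32S``; truth masks for ``cell``, ``nucleus``,
    ``lamina`` and a labeled ``globules`` array (0 = none, 1..n = globule).
    Globules are placed without overlap inside the nuclear ellipse; if a
    non-overlapping placement cannot be found within the retry cap the
    call fails.
    """
    spec = spec or IonImageSpec()
    rng = np.random.default_rng(seed)
    if nuclear_ellipse is None:
        nuclear_ellipse = (height / 2.0, width / 2.0, height * 0.28, width * 0.28)
    cy, cx, ry, rx = nuclear_ellipse
    nucleus = _ellipse_mask(height, width, (cy, cx), (ry, rx))
    cell = _ellipse_mask(height, width, (cy, cx), (ry * 1.55, rx * 1.55))
    cell &= np.ones((height, width), dtype=bool)
    lamina = np.zeros((height, width), dtype=bool)
    if lamina_ring:
        inner = _ellipse_mask(height, width, (cy, cx), (ry - 2.5, rx - 2.5))
        lamina = nucleus & ~inner

    margin = globule_radius_px + 1
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_globules:
        if tries >= max_placement_tries:
            raise RuntimeError(
                f"could not place {n_globules} non-overlapping globules in "
                f"{max_placement_tries} tries"
            )
        tries += 1
        gy = cy + (rng.random() * 2 - 1) * (ry - margin - (3 if lamina_ring else 0))
        gx = cx + (rng.random() * 2 - 1) * (rx - margin - (3 if lamina_ring else 0))
        inside = _ellipse_mask(
            height, width, (cy, cx), (ry - margin, rx - margin)
        )[int(round(gy)), int(round(gx))]
        if not inside:
            continue
        if any(
            (gy - oy) ** 2 + (gx - ox) ** 2 < (2 * globule_radius_px + 2) ** 2
            for oy, ox in centers
        ):
            continue
        centers.append((gy, gx))

    globules = np.zeros((height, width), dtype=np.int32)
    for k, (gy, gx) in enumerate(centers, start=1):
        disc = _ellipse_mask(
            height, width, (gy, gx), (globule_radius_px, globule_radius_px)
        )
        globules[disc & nucleus] = k
    globule_mask = globules > 0
    lamina &= ~globule_mask

    def region_stack(levels, globule_level=None, lamina_level=None):
        bg, cyto, nuc = levels
        plane = np.full((height, width), float(bg))
        plane[cell & ~nucleus] = cyto
        plane[nucleus] = nuc
        if lamina_level is not None:
            plane[lamina] = lamina_level
        if globule_level is not None:
            plane[globule_mask] = globule_level
        return plane

    c12 = region_stack(spec.c12_counts)
    cn = region_stack(spec.cn_counts, spec.globule_cn_counts)
    phosphorus = region_stack(
        spec.p_counts, spec.globule_p_counts, spec.lamina_p_counts if lamina_ring else None
    )
    sulfur = region_stack(spec.s_counts)
    c13_e = region_stack(
        spec.c13_enrichment,
        spec.globule_c13_enrichment,
        spec.lamina_c13_enrichment if lamina_ring else None,
    )
    n15_e = region_stack(
        spec.n15_enrichment,
        spec.globule_n15_enrichment,
        spec.lamina_n15_enrichment if lamina_ring else None,
    )
    c13 = c12 * R13C_NATURAL * (1.0 + c13_e / 100.0)
    n15 = cn * R15N_NATURAL * (1.0 + n15_e / 100.0)

    planes = {
        "12C": rng.poisson(c12),
        "13C": rng.poisson(c13),
        "12C14N": rng.poisson(cn),
        "12C15N": rng.poisson(n15),
        "31P": rng.poisson(phosphorus),
        "32S": rng.poisson(sulfur),
    }
    truth = {
        "cell": cell,
        "nucleus": nucleus,
        "lamina": lamina,
        "globules": globules,
    }
    return planes, truth


def write_ion_images(planes: dict[str, np.ndarray], outdir) -> dict[str, object]:
    """Write each plane as a 16-bit grayscale TIFF; return the paths."""
    from pathlib import Path

    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, plane in planes.items():
        path = outdir / f"{name}.tif"
        tifffile.imwrite(path, np.clip(plane, 0, 65535).astype(np.uint16))
        paths[name] = path
    return paths
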