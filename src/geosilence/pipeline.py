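"""End-to-end orchestration with a reproducibility manifest.

``run_silencing_pipeline`` chains the transcriptomic stages — load or
simulate counts, normalize, profile clusters, call silenced genes, order
genes along chromosomes, detect runs, summarize run-length distributions,
score per-cell burden, test condition differences and run the enrichment
analyses — writing every stage output as a TSV into a run directory,
together with a JSON manifest of content digests so that a re-run with the
same configuration and seed can be verified byte for byte.

``run_mims_pipeline`` does the same for the imaging side on synthetic
two-group image sets (control vs. globule-rich nuclei).
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

from . import burden as burden_mod
from . import enrichment as enrichment_mod
from . import mims as mims_mod
from . import runs as runs_mod
from . import silencing as silencing_mod
from .config import AnalysisConfig
from .io import CountDataset, write_count_dataset
from .synthetic import (
    IonImageSpec,
    SimulationSpec,
    generate_annotation,
    generate_cohort,
    generate_ion_images,
)

__all__ = ["PipelineError", "RunManifest", "run_silencing_pipeline", "run_mims_pipeline"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, row counts and digests."""

    config: dict
    seed: int
    version: str
    stage_rows: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def add_output(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[Path(path).name] = digest

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> Path:
    frame.to_csv(path, sep="\t", index=index)
    return path


def run_silencing_pipeline(
    config: AnalysisConfig,
    outdir: str | Path,
    sim_spec: SimulationSpec | None = None,
    dataset: CountDataset | None = None,
    annotation: pd.DataFrame | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    family_genes: list[str] | None = None,
    write_inputs: bool = False,
    make_figures: bool = True,
) -> RunManifest:
    """Run the full silencing analysis and write all stage outputs.

    Either provide a loaded ``dataset`` + ``annotation`` or a ``sim_spec``
    for synthetic mode (annotation is then generated). Returns the manifest;
    outputs land in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={**dataclasses.asdict(config), "somatic_chromosomes": list(config.somatic_chromosomes)},
        seed=config.random_seed if sim_spec is None else sim_spec.seed,
        version=__version__,
    )

    def stage(name):
        def decorator(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(
                    f"stage {name!r} failed: {exc}. Check the inputs listed in "
                    f"the manifest and the stage's preconditions."
                ) from exc

        return decorator

    if dataset is None:
        if sim_spec is None:
            raise PipelineError(
                "stage 'load' failed: provide a dataset or a simulation spec"
            )
        @stage("simulate")
        def _sim():
            return generate_cohort(sim_spec)

        dataset, truth = _sim
        annotation = generate_annotation(sim_spec)
        truth.write(outdir / "truth_segments.tsv")
        manifest.add_output(outdir / "truth_segments.tsv")
        if write_inputs:
            for path in write_count_dataset(dataset, outdir / "counts").values():
                manifest.add_output(path)
    elif annotation is None:
        raise PipelineError("stage 'load' failed: dataset given without annotation")
    manifest.stage_rows["cells"] = dataset.n_cells
    manifest.stage_rows["genes"] = dataset.n_genes

    @stage("silencing")
    def silence():
        return silencing_mod.call_silenced_dataset(dataset, config)

    manifest.stage_rows["silenced_calls"] = int(silence.silenced.sum())

    @stage("runs")
    def events():
        return runs_mod.detect_runs_dataset(
            silence, annotation, config.somatic_chromosomes
        )

    manifest.stage_rows["run_events"] = len(events)
    manifest.add_output(_write_tsv(events, outdir / "run_events.tsv"))

    cells_per_cluster = dataset.clusters.value_counts().sort_index()

    @stage("run_length_distribution")
    def distribution():
        return runs_mod.run_length_distribution(
            events, cells_per_cluster, config.somatic_chromosomes
        )

    manifest.add_output(
        _write_tsv(distribution.cumulative, outdir / "run_length_cumulative.tsv", index=True)
    )
    manifest.add_output(
        _write_tsv(
            runs_mod.chromosome_run_table(
                events, cells_per_cluster, config.somatic_chromosomes, config.min_run_length
            ),
            outdir / "chromosome_run_table.tsv",
            index=True,
        )
    )

    if dataset.clusters.nunique() >= 2:
        @stage("anova")
        def comparison():
            return runs_mod.compare_chromosome_frequencies(
                events,
                dataset.clusters,
                config.somatic_chromosomes,
                config.min_run_length,
            )

        manifest.add_output(
            _write_tsv(comparison.anova, outdir / "chromosome_anova.tsv", index=True)
        )
        manifest.add_output(
            _write_tsv(comparison.contrasts, outdir / "chromosome_contrasts.tsv")
        )

    @stage("burden")
    def records():
        table = burden_mod.per_cell_burden(events, dataset.cell_meta, config.min_run_length)
        return burden_mod.classify_burden(
            table, config.high_burden_threshold, config.low_burden_threshold
        )

    manifest.stage_rows["burden_records"] = len(records)
    manifest.add_output(
        _write_tsv(records.rename_axis("cell"), outdir / "burden.tsv", index=True)
    )
    manifest.add_output(
        _write_tsv(
            burden_mod.class_frequencies(records),
            outdir / "burden_class_frequencies.tsv",
            index=True,
        )
    )

    conditions = sorted(dataset.conditions.unique())
    if "control" in conditions and len(conditions) >= 2:
        pairs = [(c, "control") for c in conditions if c != "control"]

        @stage("burden_test")
        def tests():
            return burden_mod.high_burden_test(records, pairs)

        rows = [
            {
                "condition": t.condition,
                "control": t.control,
                "chi_square": t.statistic,
                "p_value": t.p_value,
                "low_expected_warning": t.low_expected_warning,
            }
            for t in tests
        ]
        manifest.add_output(
            _write_tsv(pd.DataFrame(rows), outdir / "high_burden_tests.tsv")
        )

    @stage("recurrent_genes")
    def recurrent():
        return enrichment_mod.recurrent_silenced_genes(
            silence, prevalence_threshold=config.prevalence_threshold
        )

    manifest.stage_rows["recurrent_genes"] = len(recurrent)
    manifest.add_output(_write_tsv(recurrent, outdir / "recurrent_silenced_genes.tsv"))

    if gene_sets:
        @stage("enrichment")
        def ora():
            universe = [
                g
                for g, keep in zip(
                    dataset.gene_ids, silence.evaluated.any(axis=0).to_numpy()
                )
                if keep
            ]
            return enrichment_mod.ora_test(
                recurrent["gene_id"].tolist(), universe, gene_sets
            )

        manifest.add_output(_write_tsv(ora, outdir / "ora_results.tsv"))

    if family_genes:
        @stage("family_loss")
        def family():
            expr = silencing_mod.normalize_counts(dataset, "raw")
            return enrichment_mod.family_loss_frequency(
                expr, dataset.gene_ids, family_genes, dataset.clusters
            )

        manifest.add_output(
            _write_tsv(family, outdir / "family_loss_frequency.tsv", index=True)
        )

    if make_figures:
        @stage("figures")
        def figure():
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 3.2))
            for condition in conditions:
                values = records.loc[records["condition"] == condition, "n_events"]
                ax.hist(values, bins=40, alpha=0.5, label=condition)
            ax.set_xlabel(f"silencing events per cell (runs ≥ {config.min_run_length})")
            ax.set_ylabel("cells")
            ax.legend(frameon=False)
            fig.tight_layout()
            path = outdir / "burden_histogram.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path

        manifest.add_output(figure)

    manifest.write(outdir / "manifest.json")
    return manifest


def run_mims_pipeline(
    outdir: str | Path,
    n_control: int = 5,
    n_senescent: int = 7,
    image_spec: IonImageSpec | None = None,
    n_globules_senescent: int = 3,
    globule_radius_px: int = 5,
    seed: int = 0,
    min_major_counts: int = 100,
) -> RunManifest:
    """Synthetic two-group MIMS experiment: quantify, detect, compare.

    Control nuclei carry no globules; senescent nuclei carry
    ``n_globules_senescent``. Per image the pipeline computes the ¹³C and
    ¹⁵N enrichment maps, segments the regions, measures nuclear M.A.D. of
    DNA labeling and region mean RNA labeling, and detects globules; the
    per-cell metrics are then compared between groups with the normality-
    guided two-sample test.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image_spec = image_spec or IonImageSpec()
    manifest = RunManifest(
        config={
            "n_control": n_control,
            "n_senescent": n_senescent,
            "n_globules_senescent": n_globules_senescent,
            "globule_radius_px": globule_radius_px,
            "min_major_counts": min_major_counts,
        },
        seed=seed,
        version=__version__,
    )
    if n_control < 1 or n_senescent < 1:
        raise PipelineError("stage 'simulate' failed: empty image group")

    records = []
    globule_rows = []
    for group, count, n_globules in (
        ("control", n_control, 0),
        ("senescent", n_senescent, n_globules_senescent),
    ):
        for k in range(count):
            image_seed = seed * 10_000 + (0 if group == "control" else 5_000) + k
            try:
                planes, truth = generate_ion_images(
                    n_globules=n_globules,
                    globule_radius_px=globule_radius_px,
                    spec=image_spec,
                    seed=image_seed,
                )
                c_ratio = mims_mod.enrichment_image(
                    planes["13C"], planes["12C"], mims_mod.R13C_NATURAL, min_major_counts
                )
                n_ratio = mims_mod.enrichment_image(
                    planes["12C15N"], planes["12C14N"], mims_mod.R15N_NATURAL, min_major_counts
                )
                masks = mims_mod.segment_regions(planes["31P"], planes["12C14N"])
                mad = mims_mod.mad_dispersion(c_ratio, masks.nucleus)
                means = mims_mod.region_mean_enrichment(n_ratio, masks)
                calls = mims_mod.detect_globules(
                    c_ratio,
                    n_ratio,
                    planes["31P"],
                    masks.nucleus,
                    pixel_size_nm=image_spec.pixel_size_nm,
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(
                    f"stage 'image_metrics' failed on {group} image {k}: {exc}"
                ) from exc
            records.append(
                {
                    "group": group,
                    "image": k,
                    "nuclear_mad": mad,
                    "nuclear_n15_mean": means.loc["nucleus", "mean_enrichment"],
                    "cytoplasm_n15_mean": means.loc["cytoplasm", "mean_enrichment"],
                    "n_globules_detected": len(calls),
                    "n_globules_true": n_globules,
                }
            )
            for call in calls:
                globule_rows.append(
                    {
                        "group": group,
                        "image": k,
                        "area_um2": call.area_um2,
                        "equivalent_diameter_um": call.equivalent_diameter_um,
                        "mean_c13_enrichment": call.mean_c13_enrichment,
                        "mean_n15_enrichment": call.mean_n15_enrichment,
                    }
                )

    metrics = pd.DataFrame(records)
    manifest.stage_rows["images"] = len(metrics)
    manifest.add_output(_write_tsv(metrics, outdir / "image_metrics.tsv"))
    manifest.add_output(
        _write_tsv(pd.DataFrame(globule_rows), outdir / "globule_calls.tsv")
    )

    test_rows = []
    for metric in ("nuclear_mad", "nuclear_n15_mean", "cytoplasm_n15_mean"):
        a = metrics.loc[metrics["group"] == "control", metric].to_numpy()
        b = metrics.loc[metrics["group"] == "senescent", metric].to_numpy()
        try:
            result = mims_mod.compare_groups(a, b)
        except ValueError as exc:
            raise PipelineError(f"stage 'group_tests' failed: {exc}") from exc
        test_rows.append(
            {
                "metric": metric,
                "test": result.test,
                "statistic": result.statistic,
                "p_value": result.p_value,
            }
        )
    manifest.add_output(_write_tsv(pd.DataFrame(test_rows), outdir / "group_tests.tsv"))
    manifest.write(outdir / "manifest.json")
    return manifest
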