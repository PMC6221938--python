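from pathlib import Path

import pytest
import yaml

from liquidbiopsy import io as lio
from liquidbiopsy.cnv import make_bins
from liquidbiopsy.genome import GenomeBuild
from liquidbiopsy.synthetic import (
    CopyNumberTruth,
    DropletTruth,
    default_build,
    simulate_binned_counts,
    simulate_copy_number_truth,
    simulate_droplet_well,
    simulate_variant_table,
)


@pytest.fixture(scope="session")
def toy_build():
    """Two 10 Mb chromosomes (400 bins at 50 kb)."""
    return GenomeBuild((("chr1", 10_000_000), ("chr2", 10_000_000)))


@pytest.fixture(scope="session")
def toy_binning(toy_build):
    return make_bins(toy_build, 50_000)


@pytest.fixture(scope="session")
def desk_build():
    """Default desk-scale build: 22 chromosomes, ~3,000 bins."""
    return default_build()


@pytest.fixture(scope="session")
def desk_binning(desk_build):
    return make_bins(desk_build, 50_000)


def build_case_dir(
    base: Path,
    seed: int = 0,
    timepoints: dict[str, float] | None = None,
    with_droplets: bool = True,
    with_cnv: bool = True,
    with_variants: bool = True,
    depth: float = 400.0,
) -> Path:
    """Write a fully synthetic patient case directory; returns the YAML path.

    ``timepoints`` maps timepoint name -> ctDNA fraction; droplet lambdas and
    CNV purities both scale with that fraction, so VAF and instability grow
    with it.
    """
    timepoints = timepoints or {"T1": 0.2, "T2": 0.6}
    base.mkdir(parents=True, exist_ok=True)
    doc: dict = {"patient_id": "SYN1", "disease_status": "metastatic"}

    if with_variants:
        records, _ = simulate_variant_table(
            seed=seed,
            n_per_category={"common": 4, "low_vaf": 3, "net_gene": 1, "cosmic": 2, "fail_all": 2},
        )
        lio.write_variant_table(records, base / "variants.tsv")
        doc["variants"] = "variants.tsv"

    if with_cnv:
        build = default_build(n_chromosomes=8)
        binning = make_bins(build, 50_000)
        build.to_chrom_sizes(base / "chrom.sizes")
        doc["genome"] = "chrom.sizes"
        doc["bin_size"] = 50_000
        truth = simulate_copy_number_truth(build, 8, seed=seed, copy_range=(0, 4))
        diploid = CopyNumberTruth.from_events(build, [])
        normal = simulate_binned_counts(diploid, binning, depth, seed=seed + 1)
        tumor = simulate_binned_counts(truth, binning, depth, seed=seed + 2)
        lio.write_counts(normal, base / "normal_counts.tsv")
        lio.write_counts(tumor, base / "tumor_counts.tsv")
        plasma_counts = {}
        for i, (tp, fraction) in enumerate(sorted(timepoints.items())):
            diluted = CopyNumberTruth(
                build=truth.build, segments=truth.segments, purity=fraction
            )
            counts = simulate_binned_counts(diluted, binning, depth, seed=seed + 10 + i)
            lio.write_counts(counts, base / f"plasma_{tp}_counts.tsv")
            plasma_counts[tp] = f"plasma_{tp}_counts.tsv"
        doc["cnv"] = {
            "normal_counts": "normal_counts.tsv",
            "tumor_counts": "tumor_counts.tsv",
            "plasma_counts": plasma_counts,
        }

    if with_droplets:
        droplets = {}
        for i, (tp, fraction) in enumerate(sorted(timepoints.items())):
            truth_d = DropletTruth(
                lambda_mut=0.2 * fraction, lambda_wt=0.2 * (1 - fraction)
            )
            well = simulate_droplet_well(truth_d, seed=seed + 20 + i)
            lio.write_droplet_counts([well], base / f"droplets_{tp}.tsv")
            droplets[tp] = f"droplets_{tp}.tsv"
        doc["plasma_droplets"] = droplets

    doc["config"] = {
        "quant": {"elution_volume_ul": 45.0, "plasma_volume_ml": 4.0},
        "cnv": {"logr_threshold": 0.15},
    }
    case_path = base / "case.yaml"
    case_path.write_text(yaml.safe_dump(doc))
    return case_path


@pytest.fixture()
def case_factory(tmp_path):
    def _factory(**kwargs) -> Path:
        return build_case_dir(tmp_path / "case", **kwargs)

    return _factory
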