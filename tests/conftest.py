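import pytest
from hypothesis import settings

from nestcount.annotation import (
    filter_redundant_genes,
    parse_gtf,
    subtract_nested,
    write_gtf,
)
from nestcount.fixtures import generate_scenario
from nestcount.pipeline import correct_count_files

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def run_pipeline(tmp_path, scenario: str, seed: int = 1, **count_kwargs):
    """Generate a scenario, correct its annotation, count, return results.

    Returns (table, summary, truth) after running the complete pipeline
    through the same file-level entry points the CLI uses.
    """
    gtf, sam, truth = generate_scenario(scenario, tmp_path, seed=seed)
    kept, _ = filter_redundant_genes(parse_gtf(gtf))
    annotation = subtract_nested(kept)
    full = tmp_path / f"{scenario}.full.gtf"
    introns = tmp_path / f"{scenario}.introns.gtf"
    write_gtf(annotation, full, introns)
    table, summary = correct_count_files(full, sam, hosting_gtf=introns, **count_kwargs)
    return table, summary, truth


@pytest.fixture
def pipeline_runner(tmp_path):
    def _run(scenario, seed=1, **kw):
        return run_pipeline(tmp_path, scenario, seed=seed, **kw)

    return _run


def write_sam_text(path, body_lines, contig="chrT", length=10000):
    lines = [f"@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{contig}\tLN:{length}"]
    lines += body_lines
    path.write_text("\n".join(lines) + "\n")
    return path
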