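import numpy as np
import pytest
from hypothesis import settings

from capbind import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def noiseless_curve():
    """Model-generated curve with known truth (kas=22 μM⁻¹) and no noise."""
    truth = sd.default_truth(22.0)
    design = sd.SimulationDesign(noise_sd_frac=0.0, seed=0)
    return sd.simulate_titration(truth, design), truth


@pytest.fixture
def toy_alignment_files(tmp_path):
    """Matching FASTA and Clustal encodings of a small labelled alignment."""
    rows = [
        ("a1", "A", "MKWEETSA"),
        ("a2", "A", "MKWEETSA"),
        ("b1", "B", "MKWSETSA"),
        ("b2", "B", "MKWSETSA"),
    ]
    fasta = tmp_path / "toy.fasta"
    fasta.write_text("".join(f">{sid}\n{seq}\n" for sid, _, seq in rows))
    clustal = tmp_path / "toy.aln"
    body = "\n".join(f"{sid:<10}{seq}" for sid, _, seq in rows)
    clustal.write_text(f"CLUSTAL W (1.83) multiple sequence alignment\n\n{body}\n")
    labels = {sid: fam for sid, fam, _ in rows}
    return fasta, clustal, labels
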