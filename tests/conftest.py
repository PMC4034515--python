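import numpy as np
import pytest

from tmcascade.scales import ProteinSequence


def naive_box_average(series, half_width):
    """Brute-force direct-summation moving average with edge truncation."""
    L = len(series)
    out = []
    for k in range(L):
        window = [series[j] for j in range(max(0, k - half_width), min(L, k + half_width + 1))]
        out.append(sum(window) / len(window))
    return out


def naive_cascade(series, n_max):
    """Compose brute-force box filters of widths 3, 5, 7, ... independently."""
    prev = list(series)
    passes = []
    for n in range(1, n_max + 1):
        prev = naive_box_average(prev, n)
        passes.append(prev)
    return passes


@pytest.fixture
def rng():
    return np.random.default_rng(20140511)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (id, seq) pairs."""

    def _write(records, name="input.fasta", width=60):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path

    return _write
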