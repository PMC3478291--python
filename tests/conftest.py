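import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sam(path, records, chrom="chr1", length=10_000):
    """Write a minimal SAM file.

    ``records`` are tuples (name, flag, pos0, mapq, cigar, rnext, pnext1, tlen).
    pos0 is 0-based and converted to SAM's 1-based column.
    """
    lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{chrom}\tLN:{length}"]
    for name, flag, pos0, mapq, cigar, rnext, pnext1, tlen in records:
        lines.append(
            f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t"
            f"{rnext}\t{pnext1}\t{tlen}\t*\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def simple_read(name, pos0, read_len=50, flag=0, mapq=60):
    return (name, flag, pos0, mapq, f"{read_len}M", "*", 0, 0)
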