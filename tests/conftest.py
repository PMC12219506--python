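import numpy as np
import pytest

from dispersalkit.genotype_io import GenotypeMatrix


def make_gm(calls, depths=None, samples=None, loci=None, contig_per_locus=False):
    """Build a GenotypeMatrix from a (samples x loci) array of 0/1/2/-1."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if loci is None:
        if contig_per_locus:
            loci = [(f"ctg{j}", 1, "A", "T") for j in range(L)]
        else:
            loci = [("chr1", 10 * (j + 1), "A", "T") for j in range(L)]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls, depths=depths)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def write_minimal_vcf(path, records, samples=("s0", "s1")):
    """Write a VCF from (contig, pos, ref, alt, [gt strings]) tuples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = {r[0] for r in records}
        for c in sorted(contigs):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for contig, pos, ref, alt, gts in records:
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path
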