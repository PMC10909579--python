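import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def vcf_factory(tmp_path):
    """Write a minimal single-sample VCF with FS/QD/DP/AF INFO and AD."""

    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID={contig},length={length}>\n"
        '##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">\n'
        '##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">\n'
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1\n"
    )

    def make(records, contig="ref", length=200, name="test.vcf"):
        lines = [header.format(contig=contig, length=length)]
        for rec in records:
            pos, ref, alt = rec["pos"], rec["ref"], rec["alt"]
            qual = rec.get("qual", 50)
            info = ";".join(f"{k}={rec.get(k, d)}" for k, d in
                            (("FS", 1.0), ("QD", 10.0), ("DP", 100), ("AF", 0.9))
                            if rec.get(k, d) is not None)
            ad = rec.get("AD", (5, 95))
            lines.append(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info}"
                         f"\tGT:AD\t1:{','.join(map(str, ad))}\n")
        path = tmp_path / name
        path.write_text("".join(lines))
        return path

    return make
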