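import pytest

from radmut.genome import ReferenceGenome
from radmut.variants import CandidateCall, FilteredCall, VariantClass


@pytest.fixture
def toy_ref() -> ReferenceGenome:
    # 60 bp handcrafted chromosome plus a homopolymer-rich one
    return ReferenceGenome(
        {
            "chr1": "ACGTACGTGGACGTACGTTAATTCCGGCAAATGGGATATCCCGGGTTTAAACCCGGGTTT",
            "chr2": "AAAAATTTTTCCCCCGGGGGACACACACGT",
        }
    )


def make_call(
    pos,
    ref_allele,
    alt_allele,
    vclass,
    sample="s1",
    chrom="chr1",
    af=0.5,
    end=None,
    zygosity=None,
):
    cls = CandidateCall if zygosity is None else FilteredCall
    kwargs = dict(
        sample_id=sample,
        chrom=chrom,
        pos=pos,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        variant_class=VariantClass(vclass),
        allele_frequency=af,
        end=end,
    )
    if zygosity is not None:
        kwargs["zygosity"] = zygosity
    return cls(**kwargs)


def sbs(pos, ref_allele, alt_allele, **kw):
    kw.setdefault("zygosity", "heterozygous")
    return make_call(pos, ref_allele, alt_allele, "substitution", **kw)


def deletion(pos, ref_allele, **kw):
    kw.setdefault("zygosity", "heterozygous")
    return make_call(pos, ref_allele, "", "deletion", **kw)


def insertion(pos, alt_allele, **kw):
    kw.setdefault("zygosity", "heterozygous")
    return make_call(pos, "", alt_allele, "insertion", **kw)
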