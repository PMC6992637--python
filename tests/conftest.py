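import numpy as np
import pytest

from actimr.summary_stats import HarmonisedVariant, SnpAssociation, TraitBlock


def make_harmonised(bx, sx, by, sy, outcome="outcome", eaf=0.3, n=90_000):
    """Build HarmonisedVariant records directly from effect arrays."""
    variants = []
    for i, (b1, s1, b2, s2) in enumerate(zip(bx, sx, by, sy)):
        variants.append(
            HarmonisedVariant(
                rsid=f"rs{i + 1:06d}",
                effect_allele="A",
                other_allele="G",
                exposure=TraitBlock(beta=float(b1), se=float(s1), eaf=eaf, n=n),
                outcomes={outcome: TraitBlock(beta=float(b2), se=float(s2), eaf=eaf, n=n)},
                flipped={outcome: False},
            )
        )
    return variants


def snp(rsid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01, n=1000, **kw):
    return SnpAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, eaf=eaf,
        beta=beta, se=se, n=n, **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def summary_file(tmp_path):
    """A small well-formed 2-row summary-statistics file."""
    path = tmp_path / "stats.tsv"
    path.write_text(
        "SNP\tEA\tOA\tCHR\tBP\tEAF\tBETA\tSE\tN\n"
        "rs1\tA\tG\t1\t1000\t0.25\t0.031\t0.005\t91000\n"
        "rs2\tT\tC\t2\t2000\t0.6\t-0.022\t0.004\t91000\n"
    )
    return path


CUSTOM_DIALECT = {
    "rsid": "SNP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "chromosome": "CHR",
    "position": "BP",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "n": "N",
}
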