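import pytest

from crmcat.catalogue import CatalogueRegion, NonRedundantSite
from crmcat.core import DatasetLabel, GenomicInterval, Peak


@pytest.fixture
def label():
    return DatasetLabel("GSE1", "TFX", "cellA")


def make_peak(chrom, start, end, summit=None, label=None, tf="TFX"):
    label = label or DatasetLabel("GSE1", tf, "cellA")
    if summit is None:
        summit = (start + end) // 2
    return Peak(GenomicInterval(chrom, start, end), summit, label)


def make_site(chrom, start, end, tf, summit=None):
    if summit is None:
        summit = (start + end) // 2
    return NonRedundantSite(
        interval=GenomicInterval(chrom, start, end),
        tf=tf,
        summit=summit,
        member_summits=(summit,),
    )


def make_region(chrom, start, end, tfs, n_sites=None):
    tf_set = frozenset(tfs)
    return CatalogueRegion(
        interval=GenomicInterval(chrom, start, end),
        tf_set=tf_set,
        n_sites=n_sites if n_sites is not None else len(tf_set),
    )
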