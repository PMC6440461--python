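import pytest

from mitocomp.synthetic import GenomeSpec, generate_mitogenome


@pytest.fixture(scope="session")
def ancestral():
    """One default synthetic genome (ancestral gene order) with its truth."""
    return generate_mitogenome(GenomeSpec(seed=11, label="ANC11"))


@pytest.fixture(scope="session")
def delphacid():
    """One synthetic genome with the Delphacidae-rearranged gene order."""
    return generate_mitogenome(GenomeSpec(seed=12, template="delphacid", label="DEL12"))


@pytest.fixture(scope="session")
def trio():
    """Three default genomes for multi-genome analyses."""
    out = []
    for seed in (21, 22, 23):
        g, t = generate_mitogenome(GenomeSpec(seed=seed, label=f"TRIO{seed}"))
        out.append((g, t))
    return out
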