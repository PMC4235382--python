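import numpy as np
import pytest
import yaml

from oriscape import GeneratorSpec, RunConfig, generate, generate_null

# Study conditions: 1-Mb genome, 100 planted ORIs (GC 0.317 on a 0.38
# background), ACS motif + adjacent-base Markov structure, NDR track.
STUDY_SPEC = GeneratorSpec(seed=7)

# Smaller bundle for unit tests that only need realistic structure.
SMALL_SPEC = GeneratorSpec(chrom_lengths=(150_000,), ori_count=25, seed=3)


@pytest.fixture(scope="session")
def study_bundle():
    return generate(STUDY_SPEC)


@pytest.fixture(scope="session")
def null_bundle():
    return generate_null(STUDY_SPEC)


@pytest.fixture(scope="session")
def small_bundle():
    return generate(SMALL_SPEC)


@pytest.fixture(scope="session")
def study_bundle_dir(study_bundle, tmp_path_factory):
    """Study bundle written to disk plus a pipeline config pointing at it."""
    root = tmp_path_factory.mktemp("bundle")
    paths = study_bundle.write(root / "data")
    config = {
        "genome": str(paths["genome"]),
        "oris": str(paths["oris"]),
        "genes": str(paths["genes"]),
        "tss": str(paths["tss"]),
        "track": str(paths["track"]),
        "outdir": str(root / "out"),
        "seed": 7,
    }
    cfg_path = root / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config))
    return {"paths": paths, "config_path": cfg_path, "config": config, "root": root}


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    return "".join(rng.choice(list(alphabet), size=length))
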