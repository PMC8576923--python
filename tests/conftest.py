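from __future__ import annotations

import pytest

from priobench.fixtures import DatasetSpec, generate_dataset


@pytest.fixture
def dataset_100(tmp_path):
    """A 50/50 SNP dataset with its CSV/VCF renditions on disk."""
    data, files = generate_dataset(DatasetSpec(50, 50, seed=11), tmp_path / "ds")
    return data, files


@pytest.fixture
def dataset_mixed(tmp_path):
    """A dataset containing both SNPs and INDELs."""
    data, files = generate_dataset(
        DatasetSpec(40, 40, seed=23, vtype_mix=0.3), tmp_path / "mixed"
    )
    return data, files
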