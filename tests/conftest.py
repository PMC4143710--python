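import numpy as np
import pytest

from famt2 import CaseControlDesign, CollapsedBlocks, VariantTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_ped(tmp_path):
    """Classic trio: two founders and one child."""
    path = tmp_path / "trio.ped"
    path.write_text(
        "F1 dad 0 0 1 -9\n"
        "F1 mom 0 0 2 -9\n"
        "F1 kid dad mom 1 -9\n"
    )
    return str(path)


def make_design(n_cases: int, n_controls: int) -> CaseControlDesign:
    """Cases-first design over n_cases + n_controls individuals."""
    labels = np.array([1] * n_cases + [0] * n_controls)
    return CaseControlDesign(labels=labels, order=np.arange(labels.size))


def blocks_from(X: np.ndarray, n_common: int | None = None) -> CollapsedBlocks:
    """Wrap a plain matrix as a common-variant-only (or split) block set."""
    X = np.asarray(X, dtype=float)
    t = X.shape[1] if n_common is None else n_common
    return CollapsedBlocks(
        Z=X[:, :t],
        V=X[:, t:],
        z_indices=list(range(t)),
        groups=[[t + k] for k in range(X.shape[1] - t)],
        strategy="sum-adjacent",
    )


def table_from(dosages: np.ndarray, pos=None, chrom="1") -> VariantTable:
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    return VariantTable(
        chrom=np.array([chrom] * m, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ids=np.array([f"v{k}" for k in range(m)], dtype=object),
        dosages=dosages,
        samples=[f"s{k}" for k in range(dosages.shape[0])],
    )
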