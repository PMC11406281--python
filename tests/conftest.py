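import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from screentrace.screen_io import ScreenCounts, SgRNALibrary, SgRNARecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASES = "ACGT"


def kmer(i: int, length: int = 8) -> str:
    """Deterministic unique k-mer from an integer (base-4 encoding)."""
    return "".join(BASES[(i >> (2 * j)) & 3] for j in range(length))


def build_library(genes: dict[str, int], n_ntc: int = 4, proto_len: int = 8) -> SgRNALibrary:
    """Small deterministic library: gene -> number of sgRNAs, plus NTCs."""
    records = []
    i = 0
    for gene, n in genes.items():
        for j in range(n):
            records.append(SgRNARecord(f"{gene}_sg{j + 1}", gene, kmer(i, proto_len)))
            i += 1
    for j in range(n_ntc):
        records.append(SgRNARecord(f"NTC_{j + 1}", "NTC", kmer(i, proto_len)))
        i += 1
    return SgRNALibrary(records)


def build_counts(
    count_cols: dict[str, dict[str, int]],
    arms: dict[str, str],
    doublings: dict[str, float],
    replicates: dict[str, int] | None = None,
) -> ScreenCounts:
    """ScreenCounts from explicit per-sample count dicts and metadata."""
    counts = pd.DataFrame(count_cols)
    if replicates is None:
        reps: dict[str, int] = {}
        seen: dict[str, int] = {}
        for s in counts.columns:
            seen[arms[s]] = seen.get(arms[s], 0) + 1
            reps[s] = seen[arms[s]]
        replicates = reps
    samples = pd.DataFrame(
        {
            "arm": {s: arms[s] for s in counts.columns},
            "replicate": {s: replicates[s] for s in counts.columns},
            "doublings": {s: doublings[s] for s in counts.columns},
        }
    ).rename_axis("sample")
    return ScreenCounts(counts.rename_axis("sgrna_id"), samples)


@pytest.fixture
def toy_library() -> SgRNALibrary:
    return build_library({"GENEA": 3, "GENEB": 3}, n_ntc=4)


def write_fastq(path, reads: list[str]) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
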