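"""Library QC: gel co-migration RNA-length calculator and insert sizes.

On SDS-PAGE, roughly 70 nt of cross-linked RNA retards an RNP's migration
by about 20 kDa.  Given the migration gap between two RNP species, the
minimum RNA length needed for the lighter one to co-migrate with the
heavier is therefore gap / 20 kDa x 70 nt, less the ligated adapter when
asking about the RNA insert alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import AlignedPair


@dataclass(frozen=True, slots=True)
class MigrationModel:
    nt_per_step: int = 70
    kda_per_step: float = 20.0
    adapter_nt: int = 29

    def __post_init__(self) -> None:
        if self.nt_per_step <= 0 or self.kda_per_step <= 0 or self.adapter_nt <= 0:
            raise ValueError("all migration model parameters must be positive")


def comigration_min_rna_length(
    gap_kda: float, model: MigrationModel = MigrationModel()
) -> tuple[int, int]:
    """Minimum RNA length (nt) to close a gel migration gap.

    Returns ``(with_adapter, rna_only)``: the ceiling of
    gap / kDa-per-step x nt-per-step, and the same minus the adapter
    (floored at 0).  Ceiling, not rounding: a 65 kDa gap needs 227.5 nt of
    retardation, i.e. 228 whole nucleotides.
    """
    if gap_kda < 0:
        raise ValueError("migration gap must be non-negative")
    with_adapter = math.ceil(
        gap_kda / model.kda_per_step * model.nt_per_step - 1e-9
    )
    with_adapter = max(0, with_adapter)
    return with_adapter, max(0, with_adapter - model.adapter_nt)


def median_insert_size(
    pairs_by_library: Mapping[str, Sequence[AlignedPair]],
) -> tuple[dict[str, float | None], dict[tuple[str, str], float | None]]:
    """Median |TLEN| per library, plus pairwise differences.

    Zero template lengths are excluded; an empty library yields None.  An
    even count takes the mean of the two middle values.
    """
    medians: dict[str, float | None] = {}
    for label, pairs in pairs_by_library.items():
        tlens = [abs(p.tlen) for p in pairs if p.tlen != 0]
        medians[label] = float(np.median(tlens)) if tlens else None
    diffs: dict[tuple[str, str], float | None] = {}
    for a, b in combinations(medians, 2):
        if medians[a] is None or medians[b] is None:
            diffs[(a, b)] = None
        else:
            diffs[(a, b)] = abs(medians[a] - medians[b])
    return medians, diffs
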