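"""Assembly of the per-residue feature table for one complex.

One row per interfacial residue: 12 SASA features, 3 contact counts
(residue-level), 20 interfacial composition counts (complex-level), the
chain group's sequence descriptors (AAC / PAAC / APAAC / substitution-
matrix covariances, protein-level) and, when profiles are supplied, the
40 positional PSSM features.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .sequence import (
    DEFAULT_LAMBDA,
    DEFAULT_MAX_LAG,
    DEFAULT_WEIGHT,
    PssmProfile,
    chain_descriptors,
    pssm_features,
    zero_pssm_features,
)
from .structural import structural_features
from .structure import ComplexStructure, chain_sequences, residue_index_in_chain

logger = logging.getLogger(__name__)


def extract_features(
    cx: ComplexStructure,
    pssm_profiles: Mapping[str, PssmProfile] | None = None,
    paac_lambda: int = DEFAULT_LAMBDA,
    paac_weight: float = DEFAULT_WEIGHT,
    acc_lag: int = DEFAULT_MAX_LAG,
    n_points: int | None = None,
) -> pd.DataFrame:
    """Feature table for every interfacial residue of a complex.

    Sequence descriptors are computed on the concatenated sequence of
    each chain group and attached to every residue of that group.  When
    ``pssm_profiles`` (keyed by chain id) is absent the 40 PSSM features
    are imputed as zero and ``pssm_imputed`` is set to 1.
    """
    sasa_kwargs = {} if n_points is None else {"n_points": n_points}
    struct = structural_features(cx, **sasa_kwargs)
    seqs = chain_sequences(cx.atoms)
    pos_in_chain = residue_index_in_chain(cx.atoms)
    names = cx.residue_names()

    group_seq = {
        "A": "".join(seqs[c] for c in sorted(cx.group_a)),
        "B": "".join(seqs[c] for c in sorted(cx.group_b)),
    }
    group_desc = {
        g: chain_descriptors(s, lam=paac_lambda, w=paac_weight, lag=acc_lag)
        for g, s in group_seq.items()
    }

    rows = []
    for key in sorted(struct.interface):
        chain_id, res_seq, i_code = key
        group = cx.group_of(chain_id)
        row: dict = {
            "complex": cx.source_id,
            "chain": chain_id,
            "residue": f"{res_seq}{i_code}",
            "res_name": names[key],
        }
        row.update(struct.per_residue[key])
        row.update(struct.composition)
        row.update(group_desc[group])
        if pssm_profiles and chain_id in pssm_profiles:
            row.update(pssm_features(pssm_profiles[chain_id], pos_in_chain[key]))
            row["pssm_imputed"] = 0
        else:
            row.update(zero_pssm_features())
            row["pssm_imputed"] = 1
        rows.append(row)
    if pssm_profiles is None:
        logger.info("no PSSM profiles supplied; PSSM features imputed as 0")
    return pd.DataFrame(rows)
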