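"""Study conditions: generator presets matching the reported experiments.

These constants and builders pin the synthetic generator to the measured
means of the HEK293T base-editor experiments, so the estimators can be
checked for recovery of known inputs:

* per-adenosine A-to-I means in the RSL1D1 amplicon — 1.3% with ABEmax,
  0.060% with the Cas9(D10A) nickase-only control;
* 27 of 46 RSL1D1 adenosines detectably edited (>0.1%) by ABEmax;
* 46.6% mean on-target DNA editing across seven genomic loci;
* 2.3% mean indel frequency in the 30-bp nick window;
* 0.22% transcriptome-average A-to-I frequency (coverage >= 20 filter);
* 0.068% mean A-to-I frequency across the 182 adenosines of the three
  sequenced amplicons (46 + 59 + 77) for the RNA-sparing ABEmaxAW variant.
"""

from __future__ import annotations

import numpy as np

from .models import AmpliconSpec, EditingProfile, QualityModel, SimConfig
from .simulate import make_amplicon_reference

# sequenced adenosines per amplicon: RSL1D1 46, CTNNB1 59, IP90 77
AMPLICON_ADENOSINES = {"RSL1D1": 46, "CTNNB1": 59, "IP90": 77}

ABEMAX_RSL1D1_MEAN_RATE = 0.013        # 1.3% per-adenosine A-to-I, ABEmax
CONTROL_RSL1D1_MEAN_RATE = 0.0006      # 0.060%, Cas9(D10A) nickase only
ABEMAX_DETECTABLE_OF_46 = 27           # adenosines edited above 0.1%
ABEMAXAW_THREE_AMPLICON_RATE = 0.00068  # 0.068% across 182 adenosines
DNA_ON_TARGET_RATE = 0.466             # 46.6% mean across seven loci
INDEL_RATE = 0.023                     # 2.3% in the 30-bp nick window
TRANSCRIPTOME_MEAN_RATE = 0.0022       # 0.22% transcriptome average, ABEmax

Q30 = QualityModel(mean_q=30, sd_q=0)
Q35 = QualityModel(mean_q=35, sd_q=0)


def amplicon_stand_in(name: str, seed: int, *, length: int = 240,
                      molecule: str = "cDNA",
                      target_a_protospacer_position: int | None = None,
                      ) -> AmpliconSpec:
    """Synthetic stand-in for one of the sequenced amplicons (the study's
    primer sequences are not published), with the matching adenosine count.
    RSL1D1 stand-ins embed the TadA-substrate-homology motif."""
    if name not in AMPLICON_ADENOSINES:
        raise ValueError(f"unknown amplicon {name}; choose from "
                         f"{sorted(AMPLICON_ADENOSINES)}")
    return make_amplicon_reference(
        seed, length=length, gc_fraction=0.5,
        n_adenosines=AMPLICON_ADENOSINES[name],
        embed_motif=(name == "RSL1D1"),
        target_a_protospacer_position=target_a_protospacer_position,
        molecule=molecule, name=f"{name}_standin")


def uniform_amplicon_profile(spec: AmpliconSpec, rate: float,
                             origin: str = "editor") -> EditingProfile:
    """Every sequenced adenosine edited at one uniform true rate."""
    return EditingProfile.from_pairs(
        ((int(p), rate) for p in spec.adenosine_positions), origin=origin)


def detectable_count_profile(spec: AmpliconSpec,
                             n_edited: int = ABEMAX_DETECTABLE_OF_46,
                             min_rate: float = 0.003,
                             max_rate: float = 0.03,
                             seed: int = 7) -> EditingProfile:
    """Truth profile with ``n_edited`` adenosines at rates spread over
    [min_rate, max_rate] and the remainder strictly unedited — the
    detectable-adenosine counting scenario."""
    a_pos = spec.adenosine_positions
    if n_edited > len(a_pos):
        raise ValueError("more edited sites requested than adenosines present")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(a_pos, size=n_edited, replace=False))
    rates = np.linspace(min_rate, max_rate, n_edited)
    pairs = [(int(p), float(r)) for p, r in zip(chosen, rates)]
    pairs += [(int(p), 0.0) for p in a_pos if p not in set(chosen)]
    return EditingProfile.from_pairs(sorted(pairs))


def single_site_profile(spec: AmpliconSpec, protospacer_position: int,
                        rate: float) -> EditingProfile:
    """One edited adenosine at a protospacer position (DNA on-target case)."""
    pos = spec.protospacer_to_amplicon(protospacer_position)
    return EditingProfile.from_pairs([(pos, rate)])


def amplicon_sim_config(seed: int, depth: int = 200_000,
                        indel_rate: float = 0.0) -> SimConfig:
    return SimConfig(depth=depth, read_length=240, seed=seed,
                     indel_rate=indel_rate)
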