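"""Published experimental inputs and reference statistics for the four
studied disaccharides.

Compounds (selectively 13C-labeled so the couplings are measurable):

* 4 — methyl beta-GlcNAc-(1->4)-beta-GlcNAcOCH3
* 5 — methyl beta-GlcNAc-(1->4)-beta-ManOCH3
* 6 — methyl beta-GlcNAc-(1->2)-alpha-ManOCH3
* 7 — methyl 2-deoxy-beta-Glc-(1->4)-beta-GlcOCH3

Each compound contributes four phi-sensitive couplings across its glycosidic
linkage: the conventional trans-glycosidic 2JCOC, 3JCOCC and 3JCOCH, plus the
nonconventional geminal 2JCCH (C2'-C1'-H1' pathway), usable here because the
donor residue's C2' carries an N-acetyl group (4-6) or no substituent (7), so
the coupling's secondary C-O rotational dependence is absent. Values are in
Hz +/- 0.1 Hz, measured in D2O at ~22 C; the 2JCCH sign for compound 6 was
assumed positive rather than measured.

``PUBLISHED_FITS`` and ``MD_REFERENCE`` hold the published single-state fit
statistics (constrained equations) and GLYCAM06 MD summaries for comparison.
"""

from __future__ import annotations

from .fitting import CouplingMeasurement

__all__ = [
    "COMPOUNDS",
    "experimental_couplings",
    "PSI_WINDOWS",
    "PUBLISHED_FITS",
    "MD_REFERENCE",
]

COMPOUNDS = ("4", "5", "6", "7")

# compound -> {kind: (value Hz, sign_assumed)}
_TABLE = {
    "4": {"2JCOC": (-2.0, False), "2JCCH": (1.4, False),
          "3JCOCC": (3.0, False), "3JCOCH": (4.1, False)},
    "5": {"2JCOC": (-2.0, False), "2JCCH": (1.0, False),
          "3JCOCC": (3.2, False), "3JCOCH": (4.2, False)},
    "6": {"2JCOC": (-1.8, False), "2JCCH": (0.8, True),
          "3JCOCC": (2.6, False), "3JCOCH": (3.9, False)},
    "7": {"2JCOC": (-1.9, False), "2JCCH": (2.4, False),
          "3JCOCC": (2.9, False), "3JCOCH": (4.0, False)},
}


def experimental_couplings(compound: str) -> list[CouplingMeasurement]:
    """The four measured phi-sensitive couplings of one compound."""
    if compound not in _TABLE:
        raise KeyError(f"unknown compound {compound!r}; pick from {COMPOUNDS}")
    return [
        CouplingMeasurement(kind, value, sigma=0.1, sign_assumed=assumed)
        for kind, (value, assumed) in _TABLE[compound].items()
    ]


# psi windows (degrees) used when re-parameterizing the phi equations on the
# experimentally supported psi range; compound 5's wider window compensates for
# grid structures lost to ring distortion, compound 6's is shifted because its
# (1->2) linkage prefers psi ~ +27.
PSI_WINDOWS = {
    "4": (-30.0, 30.0),
    "5": (-45.0, 45.0),
    "6": (0.0, 60.0),
    "7": (-30.0, 30.0),
}

# compound -> group -> (phi mean deg, phi CSD deg, RMSD Hz), constrained eqns
PUBLISHED_FITS = {
    "4": {"I": (34.7, 26.4, 0.18), "II": (37.3, 18.6, 0.31),
          "III": (36.6, 19.3, 0.32)},
    "5": {"I": (33.1, 22.9, 0.23), "II": (34.4, 14.5, 0.51),
          "III": (33.4, 15.9, 0.48)},
    "6": {"I": (33.5, 34.5, 0.06), "II": (36.6, 23.7, 0.55),
          "III": (35.9, 24.4, 0.49)},
    "7": {"I": (35.1, 33.5, 0.18), "II": (38.8, 13.9, 0.77),
          "III": (37.4, 16.8, 0.71)},
}

# compound -> (phi mean deg, phi CSD deg) from 1 us GLYCAM06 MD
MD_REFERENCE = {
    "4": (39.5, 12.8),
    "5": (40.2, 12.1),
    "6": (39.7, 15.0),
    "7": (40.9, 20.8),
}
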