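"""Bundled example data.

Characteristic Pi/Ri ratio table of the ELF94/ELF96 positional-isomer
ester pair (protonated molecule at 604 Th, reference ion the re-isolated
precursor), as measured on a unit-resolution ion trap from pure 100
ng/mL standards.  The six product-ion channels that pass the 5%
relative-abundance screen form the canonical overdetermined two-isomer
deconvolution matrix and are used throughout the documentation, tests
and acceptance runs.
"""

from __future__ import annotations

import numpy as np

from .leda import CharacteristicRatioTable

#: (pi_mz, ratio_ELF94, ratio_ELF96); replicate SD is 0.01 on every cell
_ELF_ROWS = (
    (392.0, 0.01, 0.27),
    (384.0, 0.09, 0.07),
    (366.0, 0.19, 0.01),
    (279.0, 0.10, 0.01),
    (253.0, 0.01, 0.11),
    (221.0, 0.38, 0.28),
)

ELF_RI_MZ = 604.0


def elf_ratio_table() -> CharacteristicRatioTable:
    """The six-equation ELF94/ELF96 characteristic-ratio table."""
    rows = np.array([[r[1], r[2]] for r in _ELF_ROWS])
    return CharacteristicRatioTable(
        isomers=("ELF94", "ELF96"),
        pi_mz=np.array([r[0] for r in _ELF_ROWS]),
        ri_mz=ELF_RI_MZ,
        ratios=rows,
        sds=np.full_like(rows, 0.01),
    )


def elf_pure_spectra(ri_abundance: float = 1.0e5) -> dict[str, list[tuple[float, dict[float, float]]]]:
    """Single-replicate pure-isomer acquisitions consistent with the table.

    Useful as input to :func:`ledams.leda.build_ratio_table`; each
    spectrum reproduces the characteristic ratios exactly.
    """
    table = elf_ratio_table()
    runs: dict[str, list[tuple[float, dict[float, float]]]] = {}
    for x, name in enumerate(table.isomers):
        pis = {float(mz): float(r * ri_abundance)
               for mz, r in zip(table.pi_mz, table.ratios[:, x])}
        runs[name] = [(ri_abundance, pis)]
    return runs
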