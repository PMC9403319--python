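import io

import numpy as np
import pytest

from glycofit.dose import DoseSeries
from glycofit.gpr import GprFile, SpotRecord, parse_gpr
from glycofit.isotherm import one_site

SAMPLE_GPR = """\
ATF\t1.0
3\t8
"Type=GenePix Results 3"
"Wavelengths=488"
"Creator=unit test"
"Block"\t"Column"\t"Row"\t"Name"\t"ID"\t"F488 Median"\t"B488 Median"\t"Flags"
1\t1\t1\t"Glycan 1"\t"1"\t5123\t100\t0
1\t2\t1\t"Glycan 1"\t"1"\t5200.5\t110\t0
"""


@pytest.fixture
def sample_gpr_text() -> str:
    return SAMPLE_GPR


@pytest.fixture
def sample_gpr() -> GprFile:
    return parse_gpr(io.StringIO(SAMPLE_GPR))


def make_gpr(rows, header=None, wavelength=488) -> GprFile:
    """Build a GprFile from (block, col, row, name, id, fg, bg, flag) tuples."""
    spots = [
        SpotRecord(block=b, column=c, row=r, name=n, glycan_id=g,
                   foreground=float(fg), background=float(bg), flag=fl)
        for b, c, r, n, g, fg, bg, fl in rows
    ]
    return GprFile(
        header=header or {"Type": "GenePix Results 3", "Wavelengths": str(wavelength)},
        spots=spots,
        wavelength=wavelength,
    )


def replicate_gpr(values_by_glycan: dict[str, list[float]], background=0.0) -> GprFile:
    """One glycan per row, one replicate per column, zero background."""
    rows = []
    for i, (gid, values) in enumerate(values_by_glycan.items(), start=1):
        for rep, v in enumerate(values, start=1):
            rows.append((1, rep, i, f"Glycan {gid}", gid, v + background, background, 0))
    return make_gpr(rows)


def model_series(gid: str, bmax: float, kd: float, ladder) -> DoseSeries:
    """Noise-free dose series drawn from the one-site model itself."""
    ladder = tuple(sorted(ladder))
    return DoseSeries(
        glycan_id=gid,
        points=[(c, float(one_site(c, bmax, kd)), 0.0) for c in ladder],
    )


LADDER = (0.04, 0.12, 0.36, 1.1, 3.3, 10.0)
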