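"""Optional adapter contract for an external ML codon-model engine.

Full maximum-likelihood codon models (site/branch/branch-site tests) are
out of scope for this package; the in-repo screen uses the counting method
in :mod:`snbp.molevol.ng86`. This module only writes a control file for,
and parses the main output of, an externally installed engine. It is not
exercised by the offline test suite.
"""

from __future__ import annotations

import re
from pathlib import Path

CONTROL_TEMPLATE = """\
seqfile = {seqfile}
treefile = {treefile}
outfile = {outfile}
noisy = 0
verbose = 0
runmode = 0
seqtype = 1
CodonFreq = {codon_freq}
model = {model}
NSsites = {ns_sites}
icode = 0
fix_kappa = 0
kappa = 2
fix_omega = {fix_omega}
omega = {omega}
"""


def write_control_file(
    path,
    seqfile: str,
    treefile: str,
    outfile: str,
    model: int = 0,
    ns_sites: int = 0,
    codon_freq: int = 2,
    fix_omega: int = 0,
    omega: float = 0.5,
) -> None:
    Path(path).write_text(
        CONTROL_TEMPLATE.format(
            seqfile=seqfile,
            treefile=treefile,
            outfile=outfile,
            model=model,
            ns_sites=ns_sites,
            codon_freq=codon_freq,
            fix_omega=fix_omega,
            omega=omega,
        )
    )


def parse_mlc(path) -> dict:
    """Extract log-likelihood, omega and kappa from an engine output file."""
    text = Path(path).read_text()
    out: dict = {}
    m = re.search(r"lnL[^=]*=\s*(-?\d+\.\d+)", text)
    if m:
        out["lnL"] = float(m.group(1))
    m = re.search(r"omega \(dN/dS\)\s*=\s*(\d+\.\d+)", text)
    if m:
        out["omega"] = float(m.group(1))
    m = re.search(r"kappa \(ts/tv\)\s*=\s*(\d+\.\d+)", text)
    if m:
        out["kappa"] = float(m.group(1))
    return out
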