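#!/usr/bin/env python
"""Protocol-yield arithmetic.

The end-to-end single-cell yield of the enrichment + sequencing protocol is
the product of its stage efficiencies: magnetic capture, release from the
sifter, FACS sort (semi-purity mode), and cDNA synthesis success.
"""

from ctcseq.pipeline import StageEfficiencies, overall_yield


def main():
    stages = {
        "capture (magnetic sifter)": 0.92,
        "release (elution)": 0.89,
        "FACS sort (semi-purity)": 0.50,
        "cDNA synthesis": 0.51,
    }
    eff = StageEfficiencies(*stages.values())
    y = overall_yield(eff)
    for name, v in stages.items():
        print(f"  {name:28s} {v:.0%}")
    print(f"  {'overall yield':28s} {y:.1%}  (~{round(y, 1):.0%})")

    ultra = StageEfficiencies(0.92, 0.89, 0.29, 0.51)
    print(f"  with ultra-purity sort (29%): {overall_yield(ultra):.1%}")


if __name__ == "__main__":
    main()
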