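"""Uniform-expectation share arithmetic and Bonferroni thresholds.

Recomputes the normalized-share bookkeeping for the three reported patient
examples (expected shares from channel counts, over/underrepresentation
factors from the observed percentage shares) and the corrected significance
levels of the two test batteries.  Writes results/worked_arithmetic.json.
"""

import json
from pathlib import Path

from preictalnet.contrasts import format_significance_level
from preictalnet.experiments import worked_share_arithmetic

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    ROOT.mkdir(parents=True, exist_ok=True)
    w = worked_share_arithmetic()
    (ROOT / "worked_arithmetic.json").write_text(json.dumps(w, indent=2))

    print("patient 1 (48 ch, 7 resected):")
    print(f"  expected share {w['p1_resected_nonlinear_expected_printed']}%  "
          f"nonlinear factor {w['p1_resected_nonlinear_factor']:.1f}  "
          f"linear factor {w['p1_resected_linear_factor']:.1f}")
    print(f"  hippocampal contacts only: expected "
          f"{w['p1_hippocampus_nonlinear_expected_printed']}%, "
          f"factor {w['p1_hippocampus_nonlinear_factor']:.1f}")
    print("patient 14 (32 ch, 14 resected):")
    print(f"  expected {w['p14_resected_nonlinear_expected_printed']}%; "
          f"HiR01 alone expected {w['p14_hir01_nonlinear_expected_printed']}%, "
          f"factor {w['p14_hir01_nonlinear_factor']:.1f}")
    print("patient 13 (76 ch, 16 resected):")
    print(f"  expected {w['p13_seizure1_nonlinear_expected_printed']}%; factors "
          f"{w['p13_seizure1_nonlinear_factor']:.1f} (seizure 1), "
          f"{w['p13_seizure2_nonlinear_factor']:.1f} (seizure 2)")
    print(f"Bonferroni: alpha/18 = "
          f"{format_significance_level(w['bonferroni_m18'])}, "
          f"alpha/6 = {w['bonferroni_m6']:.4f}")


if __name__ == "__main__":
    main()
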