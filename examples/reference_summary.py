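"""Recompute the Se/Sp summary from the packaged reference confusion matrices.

Run:  python examples/reference_summary.py
"""
from prevoid import build_report, format_report, reference_confusion_matrices

report = build_report(reference_confusion_matrices())
print(format_report(report))
# Sensitivity at the 3/4 trigger is the fraction of truly at-least-3/4
# samples that would have raised the pre-void alarm; specificity the
# fraction of below-3/4 samples left undisturbed.  The voting scheme edges
# out each individual classifier on both.
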