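"""Consensus rule table on a hand-built conflict scenario.

Seven 100-bp bins on a toy chromosome exercise every consensus
situation: agreement on normal/amplified/deleted states, a conflict with
no referee evidence, two referee-arbitrated conflicts, and a hybrid
prediction gap. Prints the merged consensus segments with the rule that
produced each.
"""

from cnvmeta import call_consensus, classify_cn, make_arbitration_fixture

fx = make_arbitration_fixture()
result = call_consensus(fx.coverage, fx.hybrid, fx.referee)

print(f"thresholds: T1={result.thresholds.t1:.2f}  T2={result.thresholds.t2:.2f}  "
      f"(estimated coverage bias {result.bias:+.2f})")
print(f"{'segment':>12}  {'CN_meta':>8}  {'error':>6}  {'class':<13}  rule")
for seg in result.segments:
    cls = classify_cn(seg.cn_meta, result.thresholds).value
    print(f"{seg.start:>5}-{seg.end:<6}  {seg.cn_meta:>8.3f}  {seg.error_score:>6.3f}  "
          f"{cls:<13}  {seg.rule_id}")

print()
print("The 0-200 segment is diploid: its second bin is a coverage/hybrid")
print("conflict with no referee evidence, so it falls back to CN 2 and")
print("merges with its agreeing neighbour. The error column is the")
print("squared disagreement between the two primary callers per segment.")
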