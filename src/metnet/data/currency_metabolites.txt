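# Heuristic preset of ubiquitous cofactor ("currency") metabolite ids.
# Edit freely: id matching is exact, one id per line, '#' starts a comment.
ATP
ADP
AMP
NAD
NADH
NADP
NADPH
H
H2O
Pi
PPi
CO2
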