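# Default spatial-trigger dictionary: spatial prepositions plus the copular
# verb set used by the Ground adjacency heuristic.  The category column is a
# placeholder (trigger matching uses surfaces only).
in	finding
of	finding
within	finding
at	finding
above	finding
below	finding
near	finding
along	finding
adjacent to	finding
beneath	finding
under	finding
into	finding
overlying	finding
is	finding
are	finding
with	finding
without	finding
show	finding
shows	finding
demonstrate	finding
demonstrates	finding
reveal	finding
reveals	finding
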