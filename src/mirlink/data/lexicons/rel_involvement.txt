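# Involvement relation predicate triggers, stored as verb lemma [+ preposition]
# or adjective + preposition. Inflections are generated at load time.
involve in
implicate in
require for
need for
play a role in
necessary for
sufficient for
crucial for
important for
essential for
dependent on
participate in
contribute to
influence
foster
affect
allow
initiate
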