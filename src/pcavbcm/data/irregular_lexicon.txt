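# Irregular surface forms with their morpheme counts.
# Irregular pasts/plurals are not decomposed (count 1) under the default
# coding convention; suppletive contractions that the suffix rules would
# miscount are listed explicitly.
# form<TAB>count
ran	1
went	1
gone	1
saw	1
came	1
got	1
took	1
fell	1
felt	1
left	1
made	1
put	1
stood	1
told	1
gave	1
knew	1
began	1
broke	1
brought	1
thought	1
caught	1
bought	1
ate	1
drank	1
spilled	2
children	1
men	1
women	1
feet	1
teeth	1
mice	1
people	1
gonna	2
wanna	2
gotta	2
cannot	2
won't	2
don't	2
doesn't	2
didn't	2
isn't	2
wasn't	2
aren't	2
weren't	2
can't	2
couldn't	2
wouldn't	2
shouldn't	2
hasn't	2
haven't	2
ain't	2
it's	2
that's	2
there's	2
he's	2
she's	2
what's	2
who's	2
here's	2
let's	2
i'm	2
i've	2
i'll	2
i'd	2
you're	2
you've	2
we're	2
we've	2
they're	2
they've	2
he'll	2
she'll	2
we'll	2
they'll	2
you'll	2
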