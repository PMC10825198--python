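# Italian stop-words: articles, prepositions, conjunctions, common auxiliaries.
# One entry per line; lines starting with '#' are comments.
il
lo
la
i
gli
le
un
uno
una
di
a
da
in
con
su
per
tra
fra
e
ed
o
od
ma
che
chi
cui
non
si
se
al
allo
alla
ai
agli
alle
del
dello
della
dei
degli
delle
dal
dallo
dalla
dai
dagli
dalle
nel
nello
nella
nei
negli
nelle
sul
sullo
sulla
sui
sugli
sulle
col
coi
come
dove
quando
mentre
dopo
prima
durante
verso
contro
senza
sopra
sotto
essere
avere
fare
questo
questa
questi
queste
quello
quella
quelli
quelle
suo
sua
suoi
sue
loro
anche
poi
più
meno
molto
poco
qui
là
vi
ci
ne
lui
lei
noi
voi
io
tu
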