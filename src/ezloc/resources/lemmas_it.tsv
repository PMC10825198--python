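braccia	braccio
gambe	gamba
mani	mano
piedi	piede
occhi	occhio
arti	arto
superiori	superiore
inferiori	inferiore
aperti	aperto
chiusi	chiuso
scosse	scossa
clonie	clonia
mioclonie	mioclonia
movimenti	movimento
automatismi	automatismo
precedenti	precedente
simili	simile
apre	aprire
chiude	chiudere
solleva	sollevare
sollevamenti	sollevamento
versioni	versione
deviazioni	deviazione
contrazioni	contrazione
vocalizzazioni	vocalizzazione
manifestazioni	manifestazione
crisi	crisi
episodi	episodio
destra	destro
sinistra	sinistro
fissa	fisso
fisse	fisso
ritmiche	ritmico
ritmici	ritmico
toniche	tonico
tonici	tonico
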