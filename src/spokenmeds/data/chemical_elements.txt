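# The 71 chemical elements removed by the element filter: elements that are
# not typically taken as a medication or supplement. Deliberately absent are
# elements commonly taken therapeutically (e.g. iron, zinc, calcium, magnesium,
# lithium, iodine, selenium).
actinium
aluminum
antimony
argon
arsenic
astatine
barium
beryllium
bromine
cadmium
carbon
cerium
cesium
chlorine
cobalt
copper
dysprosium
erbium
europium
fluorine
francium
gallium
germanium
gold
hafnium
helium
hydrogen
indium
iridium
krypton
lanthanum
lead
lutetium
mercury
molybdenum
neodymium
neon
nickel
niobium
osmium
palladium
phosphorus
platinum
polonium
potassium
promethium
protactinium
radium
radon
rhenium
rubidium
ruthenium
samarium
scandium
silicon
silver
strontium
tantalum
tellurium
terbium
thorium
thallium
tin
titanium
tungsten
uranium
vanadium
xenon
ytterbium
yttrium
zirconium
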