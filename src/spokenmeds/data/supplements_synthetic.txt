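# Common herbs and supplements added as medication mentions regardless of
# lexicon coverage. Synthetic stand-in authored for this package, modelled on
# the MedlinePlus herb/supplement index (which is not redistributable here);
# edit or replace with a vendored copy as needed. Multi-word terms allowed.
ginkgo
ginkgo biloba
ginseng
echinacea
turmeric
curcumin
fish oil
omega 3
krill oil
st john's wort
melatonin
glucosamine
chondroitin
saw palmetto
valerian
valerian root
chamomile
lavender
garlic
ginger
cinnamon
elderberry
milk thistle
black cohosh
evening primrose oil
flaxseed
flaxseed oil
aloe vera
cranberry
green tea extract
coenzyme q10
biotin
folate
folic acid
probiotic
probiotics
zinc
magnesium
creatine
ashwagandha
kava
feverfew
goldenseal
hawthorn
licorice root
bilberry
dandelion root
peppermint oil
red yeast rice
dhea
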