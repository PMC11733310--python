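# Raw land-cover / crop label -> harmonized 13-class scheme.
# Tab-separated; labels are matched case-insensitively. Edit freely:
# any raw vocabulary can be regrouped here without touching code.
#
# --- natural-vegetation layer labels ---
agriculture	miscellaneous
barren	barren/other
barren/other	barren/other
conifer	conifer
conifer forest	conifer
conifer woodland	conifer
desert	desert
desert shrub	desert
desert woodland	desert
grassland	grassland
grass	grassland
hardwood	hardwood
hardwood forest	hardwood
hardwood woodland	hardwood
herbaceous	herbaceous
wet herbaceous	herbaceous
shrub	shrub
shrubland	shrub
urban	urban
water	water/wetland
wetland	water/wetland
water/wetland	water/wetland
miscellaneous	miscellaneous
# --- crop-parcel layer labels ---
rice	rice
wild rice	rice
almonds	fruits/nuts/vineyards
walnuts	fruits/nuts/vineyards
pistachios	fruits/nuts/vineyards
grapes	fruits/nuts/vineyards
vineyard	fruits/nuts/vineyards
olives	fruits/nuts/vineyards
citrus	fruits/nuts/vineyards
pears	fruits/nuts/vineyards
peaches/nectarines	fruits/nuts/vineyards
plums/prunes/apricots	fruits/nuts/vineyards
cherries	fruits/nuts/vineyards
fruits/nuts/vineyards	fruits/nuts/vineyards
alfalfa	row/field crops
corn	row/field crops
tomatoes	row/field crops
sunflower	row/field crops
safflower	row/field crops
wheat	row/field crops
beans	row/field crops
cucurbits	row/field crops
onions/garlic	row/field crops
potatoes	row/field crops
cotton	row/field crops
mixed pasture	row/field crops
row/field crops	row/field crops
idle	miscellaneous
fallow	miscellaneous
managed wetland	water/wetland
urban/developed	urban
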